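"""Low-resolution placement: rigid-body ligand and water moves with clash retries.

Three protocols share these movers:

* *standard*: ligand translate (<=5 A ball, 50 tries) -> rotate (<=1000
  tries) -> slide into vdW contact.
* *protein-centric*: standard ligand moves plus an independent water
  translate (<=4 A ball) and full reorientation, then slide.
* *ligand-centric*: waters ride the ligand's translation, make small (<=1 A)
  independent moves, rotate with the ligand as one rigid body, reorient
  independently, then slide together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import random_in_ball, random_rotation, rotate_about
from .scoring import ScoreFunction
from .structure import Pose, WaterdockError

WATER_OXYGEN_RADIUS = 1.52


@dataclass
class LowResParams:
    """Constants of the low-resolution search (distances in Angstrom)."""

    translate_radius: float = 5.0  # ligand translation ball
    water_translate_radius: float = 4.0  # protein-centric water ball
    water_shift_radius: float = 1.0  # ligand-centric independent water moves
    translate_tries: int = 50
    rotate_tries_ligand: int = 1000
    rotate_tries_water: int = 100
    water_cycles: int = 50
    slide_step: float = 0.1
    centroid_clash_radius: float = 2.25  # protein atom distance counting as
    # a clash with the ligand centroid
    clash_factor: float = 0.7  # heavy-atom clash at d < factor * (ri + rj)
    interface_radius: float = 8.0  # protein shell defining the slide target


DEFAULT_LOWRES = LowResParams()


def _protein_heavy(pose: Pose):
    m = pose.structure.heavy_mask
    return pose.structure.coords[m], pose.structure.vdw[m]


def _centroid_clashes(centroid, pcoords, radius: float) -> bool:
    if len(pcoords) == 0:
        return False
    return bool(np.min(np.linalg.norm(pcoords - centroid, axis=1)) < radius)


def _atoms_clash(coords, radii, pcoords, pradii, factor: float) -> bool:
    if len(pcoords) == 0 or len(coords) == 0:
        return False
    d = cdist(coords, pcoords)
    return bool(np.any(d < factor * (radii[:, None] + pradii[None, :])))


def _shift_ligand(pose: Pose, delta, carry_waters: bool) -> None:
    pose.ligand.coords = pose.ligand.coords + delta
    if carry_waters and len(pose.waters):
        pose.waters.oxygens = pose.waters.oxygens + delta
        pose.waters.hydrogens = pose.waters.hydrogens + delta


def translate_ligand(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
    carry_waters: bool = False,
) -> Pose:
    """Random ligand translation within a ball about the starting centroid.

    Each try re-draws from the original centroid; the first try whose new
    centroid passes the centroid-clash test is accepted.  After
    ``translate_tries`` failures the try with the lowest repulsive score is
    accepted instead.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    pose = pose.copy()
    if params.translate_radius == 0.0:
        return pose
    pcoords, _ = _protein_heavy(pose)
    start = pose.ligand.centroid.copy()
    candidates = []
    for _ in range(params.translate_tries):
        delta = random_in_ball(params.translate_radius, rng)
        if not _centroid_clashes(start + delta, pcoords, params.centroid_clash_radius):
            _shift_ligand(pose, delta, carry_waters)
            return pose
        candidates.append(delta)
    # no clash-free centroid: keep the least repulsive placement
    best, best_rep = None, np.inf
    for delta in candidates:
        trial = pose.copy()
        _shift_ligand(trial, delta, carry_waters)
        rep = sf.breakdown(trial).repulsive
        if rep < best_rep:
            best, best_rep = delta, rep
    _shift_ligand(pose, best, carry_waters)
    return pose


def rotate_ligand(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
    carry_waters: bool = False,
) -> Pose:
    """Uniform random rotations about the ligand centroid; first fully
    clash-free orientation wins, else the best attractive+repulsive one."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    pose = pose.copy()
    if params.rotate_tries_ligand <= 0:
        return pose
    pcoords, pradii = _protein_heavy(pose)
    center = pose.ligand.centroid.copy()
    lheavy = pose.ligand.heavy_mask
    start_lig = pose.ligand.coords.copy()
    start_ox = pose.waters.oxygens.copy()
    start_hy = pose.waters.hydrogens.copy()

    def apply(R):
        pose.ligand.coords = rotate_about(start_lig, center, R)
        if carry_waters and len(pose.waters):
            pose.waters.oxygens = rotate_about(start_ox, center, R)
            pose.waters.hydrogens = rotate_about(
                start_hy.reshape(-1, 3), center, R
            ).reshape(start_hy.shape)

    rotations = []
    for _ in range(params.rotate_tries_ligand):
        R = random_rotation(rng)
        apply(R)
        clash = _atoms_clash(
            pose.ligand.coords[lheavy],
            pose.ligand.vdw[lheavy],
            pcoords,
            pradii,
            params.clash_factor,
        )
        if carry_waters and not clash and len(pose.waters):
            clash = _atoms_clash(
                pose.waters.oxygens,
                np.full(len(pose.waters), WATER_OXYGEN_RADIUS),
                pcoords,
                pradii,
                params.clash_factor,
            )
        if not clash:
            return pose
        rotations.append(R)
    best, best_score = None, np.inf
    for R in rotations:
        apply(R)
        s = sf.attractive_repulsive(pose)
        if s < best_score:
            best, best_score = R, s
    apply(best)
    return pose


def slide_together(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    carry_waters: bool = False,
) -> Pose:
    """Slide the ligand toward the protein until first vdW contact, then
    back off one step.  Direction: ligand centroid toward the centroid of
    protein atoms within ``interface_radius`` of the ligand (whole-protein
    fallback)."""
    pose = pose.copy()
    pcoords, pradii = _protein_heavy(pose)
    if len(pcoords) == 0:
        raise WaterdockError("no protein atoms to slide toward")
    lheavy = pose.ligand.heavy_mask
    lcoords = pose.ligand.coords[lheavy]
    lradii = pose.ligand.vdw[lheavy]

    d = cdist(lcoords, pcoords)
    near = np.any(d <= params.interface_radius, axis=0)
    target = pcoords[near].mean(axis=0) if near.any() else pcoords.mean(axis=0)
    direction = target - pose.ligand.centroid
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise WaterdockError("slide direction degenerate: coincident centroids")
    direction /= norm

    def in_contact() -> bool:
        dd = cdist(pose.ligand.coords[lheavy], pcoords)
        return bool(np.any(dd <= lradii[:, None] + pradii[None, :]))

    if in_contact():
        return pose
    max_steps = int(np.ceil((norm + 20.0) / params.slide_step))
    for _ in range(max_steps):
        _shift_ligand(pose, params.slide_step * direction, carry_waters)
        if in_contact():
            _shift_ligand(pose, -params.slide_step * direction, carry_waters)
            return pose
    return pose


def move_water_protein_centric(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Translate each water uniformly in a ball about its input oxygen with
    the 50-try clash/acceptance contract, and resample its orientation."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    pose = pose.copy()
    pcoords, pradii = _protein_heavy(pose)
    for w in range(len(pose.waters)):
        start = pose.waters.oxygens[w].copy()
        chosen = None
        candidates = []
        for _ in range(params.translate_tries):
            delta = random_in_ball(params.water_translate_radius, rng)
            o = start + delta
            if not _atoms_clash(
                o[None, :],
                np.array([WATER_OXYGEN_RADIUS]),
                pcoords,
                pradii,
                params.clash_factor,
            ):
                chosen = delta
                break
            candidates.append(delta)
        if chosen is None:
            best, best_rep = None, np.inf
            for delta in candidates:
                trial = pose.copy()
                trial.waters.oxygens[w] = start + delta
                trial.waters.hydrogens[w] += delta
                rep = sf.breakdown(trial).repulsive
                if rep < best_rep:
                    best, best_rep = delta, rep
            chosen = best
        pose.waters.oxygens[w] = start + chosen
        pose.waters.hydrogens[w] += chosen
        _reorient_water(pose, w, random_rotation(rng))
    return pose


def _reorient_water(pose: Pose, w: int, R: np.ndarray) -> None:
    o = pose.waters.oxygens[w]
    pose.waters.hydrogens[w] = (pose.waters.hydrogens[w] - o) @ R.T + o


def _water_orientation_energy(pose: Pose, w: int, sf: ScoreFunction) -> float:
    """Orientation-dependent part of the score for one water: its donor
    hydrogen-bond terms against nearby acceptor-capable heavy atoms."""
    wts = sf.weights
    o = pose.waters.oxygens[w]
    acceptors = []
    for arr in (pose.structure, pose.ligand):
        heavy = arr.heavy_mask
        for i in np.where(heavy)[0]:
            if arr.roles[i] in ("acceptor", "both"):
                acceptors.append(arr.coords[i])
    for v in range(len(pose.waters)):
        if v != w:
            acceptors.append(pose.waters.oxygens[v])
    e = 0.0
    for a in acceptors:
        d = float(np.linalg.norm(a - o))
        if d <= 1e-6 or d > wts.hb_d_zero:
            continue
        f = np.clip((wts.hb_d_zero - d) / (wts.hb_d_zero - wts.hb_d_full), 0, 1)
        g = 0.0
        for h in range(2):
            hpos = pose.waters.hydrogens[w, h]
            v1 = o - hpos
            v2 = a - hpos
            c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
            g = max(g, float(np.clip((-0.5 - c) / 0.5, 0.0, 1.0)))
        e += -wts.hbond * f * g
    return e


def reorient_waters(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Per-water orientation search: up to ``rotate_tries_water`` random
    orientations, keeping the best-scoring one.

    With a heavy-atom-only Lennard-Jones, water orientation enters the score
    solely through the hydrogen-bond term, so that is the objective here.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    pose = pose.copy()
    for w in range(len(pose.waters)):
        best_h = pose.waters.hydrogens[w].copy()
        best_e = _water_orientation_energy(pose, w, sf)
        for _ in range(params.rotate_tries_water):
            _reorient_water(pose, w, random_rotation(rng))
            e = _water_orientation_energy(pose, w, sf)
            if e < best_e:
                best_e = e
                best_h = pose.waters.hydrogens[w].copy()
        pose.waters.hydrogens[w] = best_h
    return pose


def shift_waters_independently(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Ligand-centric stage 2: per water, up to ``water_cycles`` uniform
    <=1 A oxygen moves; the first non-clashing move is accepted (lowest
    repulsive fallback)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    pose = pose.copy()
    pcoords, pradii = _protein_heavy(pose)
    lheavy = pose.ligand.heavy_mask
    obstacles = np.vstack([pcoords, pose.ligand.coords[lheavy]])
    obs_radii = np.concatenate([pradii, pose.ligand.vdw[lheavy]])
    for w in range(len(pose.waters)):
        start = pose.waters.oxygens[w].copy()
        chosen = None
        candidates = []
        for _ in range(params.water_cycles):
            delta = random_in_ball(params.water_shift_radius, rng)
            if not _atoms_clash(
                (start + delta)[None, :],
                np.array([WATER_OXYGEN_RADIUS]),
                obstacles,
                obs_radii,
                params.clash_factor,
            ):
                chosen = delta
                break
            candidates.append(delta)
        if chosen is None:
            best, best_rep = None, np.inf
            for delta in candidates:
                trial = pose.copy()
                trial.waters.oxygens[w] = start + delta
                trial.waters.hydrogens[w] += delta
                rep = sf.breakdown(trial).repulsive
                if rep < best_rep:
                    best, best_rep = delta, rep
            chosen = best
        pose.waters.oxygens[w] = start + chosen
        pose.waters.hydrogens[w] += chosen
    return pose


def move_waters_ligand_centric(
    pose: Pose,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Staged ligand-centric placement: waters ride the ligand translation,
    shift independently by <=1 A, rotate with the ligand as a rigid body,
    then reorient independently."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    pose = translate_ligand(pose, params, rng, sf, carry_waters=True)
    if len(pose.waters):
        pose = shift_waters_independently(pose, params, rng, sf)
    pose = rotate_ligand(pose, params, rng, sf, carry_waters=True)
    if len(pose.waters):
        pose = reorient_waters(pose, params, rng, sf)
    return pose


def run_low_res(
    pose: Pose,
    protocol: str,
    params: LowResParams = DEFAULT_LOWRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Run one low-resolution placement under the named protocol."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    if protocol == "standard":
        pose = translate_ligand(pose, params, rng, sf)
        pose = rotate_ligand(pose, params, rng, sf)
        pose = slide_together(pose, params)
    elif protocol == "protein_centric":
        pose = translate_ligand(pose, params, rng, sf)
        pose = rotate_ligand(pose, params, rng, sf)
        if len(pose.waters):
            pose = move_water_protein_centric(pose, params, rng, sf)
        pose = slide_together(pose, params)
    elif protocol == "ligand_centric":
        pose = move_waters_ligand_centric(pose, params, rng, sf)
        pose = slide_together(pose, params, carry_waters=True)
    else:
        raise WaterdockError(f"unknown protocol {protocol!r}")

    pcoords, pradii = _protein_heavy(pose)
    lheavy = pose.ligand.heavy_mask
    strained = _atoms_clash(
        pose.ligand.coords[lheavy],
        pose.ligand.vdw[lheavy],
        pcoords,
        pradii,
        params.clash_factor,
    )
    if not strained and len(pose.waters):
        strained = _atoms_clash(
            pose.waters.oxygens,
            np.full(len(pose.waters), WATER_OXYGEN_RADIUS),
            pcoords,
            pradii,
            params.clash_factor,
        )
    pose.strained = bool(strained)
    return pose
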