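"""High-resolution Monte-Carlo refinement.

Six cycles of {small rigid-body perturbation -> side-chain repacking ->
torsion-space minimization} with Metropolis acceptance on the total score,
followed by a final minimization that also frees backbone torsions near the
ligand.  Rigid-body perturbations are <=0.1 A translations and <=5 degree
rotations of the ligand and of each water independently.  Repacking is
restricted to residues within 6 A of any ligand atom (extended to residues
near waters); final minimization frees phi/psi within 7 A.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import axis_angle_matrix, dihedral, random_in_ball, random_small_rotation, rotate_about
from .rotamers import CHI_DEFS, rotamer_angles
from .scoring import ScoreFunction, _pose_coords, score_pose
from .structure import Pose, Structure

__all__ = [
    "HighResParams",
    "perturb_rigid_body",
    "repack_sidechains",
    "minimize_torsions",
    "run_high_res",
    "metropolis_accept",
    "interface_residues",
]


@dataclass
class HighResParams:
    """Constants of the refinement stage."""

    trans_mag: float = 0.1  # A, rigid-body translation magnitude
    rot_mag: float = 5.0  # degrees, rigid-body rotation magnitude
    n_cycles: int = 6
    repack_radius: float = 6.0  # A, side-chain shell around ligand/waters
    final_min_radius: float = 7.0  # A, backbone shell for final minimization
    mc_temperature: float = 0.6  # Metropolis temperature, energy units
    full_repack_cycle: int = 3  # cycle using joint repacking (others: trials)
    anneal_proposals: int = 60  # proposals per simulated-annealing stage
    min_tol: float = 1e-4  # rad, smallest line-search step
    min_improve: float = 1e-6  # energy units, per-iteration stopping threshold
    min_max_iter: int = 200


DEFAULT_HIGHRES = HighResParams()


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion; always accepts downhill moves."""
    if delta_e <= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < np.exp(-delta_e / temperature))


def perturb_rigid_body(
    pose: Pose,
    params: HighResParams = DEFAULT_HIGHRES,
    rng: np.random.Generator | None = None,
) -> Pose:
    """Independent small translations/rotations of ligand and each water."""
    rng = rng if rng is not None else np.random.default_rng(0)
    pose = pose.copy()
    center = pose.ligand.centroid
    R = random_small_rotation(params.rot_mag, rng)
    delta = random_in_ball(params.trans_mag, rng)
    pose.ligand.coords = rotate_about(pose.ligand.coords, center, R) + delta
    for w in range(len(pose.waters)):
        pts = np.vstack([pose.waters.oxygens[w], pose.waters.hydrogens[w]])
        c = pts.mean(axis=0)
        Rw = random_small_rotation(params.rot_mag, rng)
        dw = random_in_ball(params.trans_mag, rng)
        moved = rotate_about(pts, c, Rw) + dw
        pose.waters.oxygens[w] = moved[0]
        pose.waters.hydrogens[w] = moved[1:]
    return pose


def interface_residues(pose: Pose, radius: float) -> list[tuple[str, int]]:
    """Residues with any atom within ``radius`` of any ligand atom or water
    oxygen (the water-extended interface definition)."""
    probes = [pose.ligand.coords]
    if len(pose.waters):
        probes.append(pose.waters.oxygens)
    probe = np.vstack(probes)
    out = []
    for chain, num, _rname, idx in pose.structure.residues():
        d = cdist(pose.structure.coords[idx], probe)
        if np.any(d <= radius):
            out.append((chain, num))
    return out


def _set_chi(st: Structure, chain: str, num: int, chi_def, target_deg: float) -> None:
    idx = {st.names[i]: int(i) for i in st.residue_index[(chain, num)]}
    try:
        a, b, c, d = (idx[n] for n in chi_def.atoms)
    except KeyError:
        return  # incomplete residue: leave fixed
    current = dihedral(st.coords[a], st.coords[b], st.coords[c], st.coords[d])
    delta = np.deg2rad(target_deg) - current
    axis = st.coords[c] - st.coords[b]
    R = axis_angle_matrix(axis, delta)
    moving = [idx[n] for n in chi_def.moving if n in idx]
    if not moving:
        return
    st.coords[moving] = rotate_about(st.coords[moving], st.coords[b], R)


def _apply_assignment(pose: Pose, residues, assignment) -> Pose:
    trial = pose.copy()
    for (chain, num, resname), chis in zip(residues, assignment):
        for chi_def, ang in zip(CHI_DEFS[resname], chis):
            _set_chi(trial.structure, chain, num, chi_def, ang)
    return trial


def repack_sidechains(
    pose: Pose,
    mode: str = "trials",
    params: HighResParams = DEFAULT_HIGHRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Discrete side-chain optimization over the interface shell.

    ``trials``: one sweep, each residue takes its argmin rotamer with the
    rest of the pose fixed.  ``repack``: seeded simulated annealing over the
    joint assignment with best-seen bookkeeping, so the returned pose never
    scores worse than the trials result on the same shell.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    shell = interface_residues(pose, params.repack_radius)
    residues = []
    rotsets = []
    for chain, num, rname, idx in pose.structure.residues():
        if (chain, num) not in shell:
            continue
        rots = rotamer_angles(rname)
        if rots is None:
            warnings.warn(f"residue {rname} {chain}{num} not in rotamer library; fixed")
            continue
        if len(rots) <= 1 and rots == [()]:
            continue  # no rotatable chi
        residues.append((chain, num, rname))
        rotsets.append(rots)
    if not residues:
        return pose.copy()

    if mode == "trials":
        current = pose.copy()
        for r, (chain, num, rname) in enumerate(residues):
            best_pose, best_e = None, np.inf
            for chis in rotsets[r]:
                trial = current.copy()
                for chi_def, ang in zip(CHI_DEFS[rname], chis):
                    _set_chi(trial.structure, chain, num, chi_def, ang)
                e = sf.total(trial)
                if e < best_e:
                    best_pose, best_e = trial, e
            current = best_pose
        return current
    if mode != "repack":
        raise ValueError(f"unknown repack mode {mode!r}")

    # simulated annealing over the joint assignment
    assignment = [rots[0] for rots in rotsets]
    current_pose = _apply_assignment(pose, residues, assignment)
    current_e = sf.total(current_pose)
    best_assignment, best_e = list(assignment), current_e
    temperatures = np.geomspace(2.0, 0.05, params.anneal_proposals)
    for t in temperatures:
        r = int(rng.integers(len(residues)))
        choice = rotsets[r][int(rng.integers(len(rotsets[r])))]
        trial_assignment = list(assignment)
        trial_assignment[r] = choice
        trial_pose = _apply_assignment(pose, residues, trial_assignment)
        e = sf.total(trial_pose)
        if metropolis_accept(e - current_e, t, rng):
            assignment, current_e = trial_assignment, e
            if e < best_e:
                best_assignment, best_e = list(assignment), e
    # coordinate-descent polish from the best-seen assignment: sweep
    # per-residue conditional argmins until no residue changes, so the
    # result is exact on shells whose residues do not interact
    assignment = list(best_assignment)
    improved = True
    while improved:
        improved = False
        for r in range(len(residues)):
            for choice in rotsets[r]:
                trial_assignment = list(assignment)
                trial_assignment[r] = choice
                e = sf.total(_apply_assignment(pose, residues, trial_assignment))
                if e < best_e - 1e-12:
                    assignment, best_e = trial_assignment, e
                    improved = True
    return _apply_assignment(pose, residues, assignment)


# ---------------------------------------------------------------------------
# torsion minimization


@dataclass
class _TorsionDOF:
    target: str  # "ligand" | "protein"
    axis: tuple[int, int]  # atom indices (b, c): rotation about b->c
    moving: list[int] = field(default_factory=list)

    @property
    def moving_idx(self) -> np.ndarray:
        cached = getattr(self, "_moving_idx", None)
        if cached is None:
            cached = np.asarray(self.moving, dtype=np.intp)
            object.__setattr__(self, "_moving_idx", cached)
        return cached


def _ligand_torsion_dofs(pose: Pose) -> list[_TorsionDOF]:
    dofs = []
    adj = pose.ligand.neighbors()
    for (_i, j, k, _l) in pose.ligand.rotatable_torsions:
        # atoms on the k side of bond j-k move
        seen = {j, k}
        stack = [k]
        moving = []
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    moving.append(v)
                    stack.append(v)
        if moving:
            dofs.append(_TorsionDOF("ligand", (j, k), sorted(moving)))
    return dofs


def _sidechain_dofs(pose: Pose, shell) -> list[_TorsionDOF]:
    dofs = []
    for chain, num, rname, idx in pose.structure.residues():
        if (chain, num) not in shell or rname not in CHI_DEFS:
            continue
        names = {pose.structure.names[i]: int(i) for i in idx}
        for chi_def in CHI_DEFS[rname]:
            if not all(n in names for n in chi_def.atoms[1:3]):
                continue
            moving = [names[n] for n in chi_def.moving if n in names]
            if moving:
                dofs.append(
                    _TorsionDOF(
                        "protein",
                        (names[chi_def.atoms[1]], names[chi_def.atoms[2]]),
                        moving,
                    )
                )
    return dofs


def _backbone_dofs(pose: Pose, shell) -> list[_TorsionDOF]:
    """phi/psi of shell residues; downstream residues of the same chain move."""
    st = pose.structure
    dofs = []
    for chain, num, _rname, idx in st.residues():
        if (chain, num) not in shell:
            continue
        names = {st.names[i]: int(i) for i in idx}
        downstream = [
            int(i)
            for c2, n2, _r2, idx2 in st.residues()
            if c2 == chain and n2 > num
            for i in idx2
        ]
        if "N" in names and "CA" in names:
            # phi: rotation about N-CA moves everything past CA
            moving = [i for n, i in names.items() if n not in ("N", "CA", "H")]
            moving += downstream
            has_prev = (chain, num - 1) in st.residue_index
            if moving and has_prev:
                dofs.append(_TorsionDOF("protein", (names["N"], names["CA"]), moving))
        if "CA" in names and "C" in names:
            moving = [names[n] for n in ("O", "OXT") if n in names] + downstream
            if moving:
                dofs.append(_TorsionDOF("protein", (names["CA"], names["C"]), moving))
    return dofs


class _FlatDOF:
    """A torsion DOF with indices into the concatenated coordinate array."""

    __slots__ = ("b", "c", "moving")

    def __init__(self, b: int, c: int, moving: np.ndarray):
        self.b = b
        self.c = c
        self.moving = moving


def _flatten_dofs(dofs: list[_TorsionDOF], n_protein: int) -> list[_FlatDOF]:
    flat = []
    for dof in dofs:
        off = n_protein if dof.target == "ligand" else 0
        flat.append(
            _FlatDOF(dof.axis[0] + off, dof.axis[1] + off, dof.moving_idx + off)
        )
    return flat


def _apply_one(coords: np.ndarray, fd: _FlatDOF, ang: float) -> None:
    """Rotate ``fd.moving`` about the b->c axis by ``ang`` (radians), in place.

    Rodrigues rotation written out componentwise: the moving sets are tiny
    (1-2 atoms for chis), so numpy call overhead would dominate.
    """
    if ang == 0.0:
        return
    ox, oy, oz = coords[fd.b].tolist()
    ax, ay, az = coords[fd.c].tolist()
    ax -= ox
    ay -= oy
    az -= oz
    inv = 1.0 / math.sqrt(ax * ax + ay * ay + az * az)
    ax *= inv
    ay *= inv
    az *= inv
    cos_a, sin_a = math.cos(ang), math.sin(ang)
    omc = 1.0 - cos_a
    moving = fd.moving
    if len(moving) <= 8:
        rows = coords[moving].tolist()
        for r in rows:
            px, py, pz = r
            px -= ox
            py -= oy
            pz -= oz
            dot = (px * ax + py * ay + pz * az) * omc
            r[0] = px * cos_a + (ay * pz - az * py) * sin_a + dot * ax + ox
            r[1] = py * cos_a + (az * px - ax * pz) * sin_a + dot * ay + oy
            r[2] = pz * cos_a + (ax * py - ay * px) * sin_a + dot * az + oz
        coords[moving] = rows
    else:
        p = coords[moving]
        px = p[:, 0] - ox
        py = p[:, 1] - oy
        pz = p[:, 2] - oz
        dot = (px * ax + py * ay + pz * az) * omc
        out = np.empty_like(p)
        out[:, 0] = px * cos_a + (ay * pz - az * py) * sin_a + dot * ax + ox
        out[:, 1] = py * cos_a + (az * px - ax * pz) * sin_a + dot * ay + oy
        out[:, 2] = pz * cos_a + (ax * py - ay * px) * sin_a + dot * az + oz
        coords[moving] = out


def _apply_flat(coords, flat, angles, start: int = 0) -> None:
    """Apply ``flat[start:]`` sequentially with the matching angles."""
    for k in range(start, len(flat)):
        _apply_one(coords, flat[k], angles[k])


def minimize_torsions(
    pose: Pose,
    scope: str = "sidechain+ligand",
    params: HighResParams = DEFAULT_HIGHRES,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Numerical-gradient descent on torsional degrees of freedom.

    ``sidechain+ligand`` frees interface side-chain chis and ligand
    torsions; ``final`` additionally frees backbone phi/psi within
    ``final_min_radius``.  Steepest descent with a batched forward-difference
    gradient (h = 1e-4 rad) and an adaptive step-halving line search; stops
    when one iteration improves the energy by less than ``min_improve``.
    The energy never increases.
    """
    sf = sf or ScoreFunction()
    pose = pose.copy()
    shell6 = set(interface_residues(pose, params.repack_radius))
    dofs = _ligand_torsion_dofs(pose) + _sidechain_dofs(pose, shell6)
    if scope == "final":
        shell7 = set(interface_residues(pose, params.final_min_radius))
        dofs += _backbone_dofs(pose, shell7)
    elif scope != "sidechain+ligand":
        raise ValueError(f"unknown minimization scope {scope!r}")
    if not dofs:
        return pose

    n_p = len(pose.structure)
    n_l = len(pose.ligand)
    flat = _flatten_dofs(dofs, n_p)
    base = _pose_coords(pose)
    n_dof = len(flat)
    x = np.zeros(n_dof)

    def apply_x(xv) -> np.ndarray:
        c = base.copy()
        _apply_flat(c, flat, xv)
        return c

    def energy(xv) -> float:
        return sf.total_coords(pose, apply_x(xv))

    h = 1e-4
    e_cur = energy(x)
    stack = np.empty((n_dof,) + base.shape)

    def gradient(xv) -> np.ndarray:
        # all forward-difference displacements scored in one batched call;
        # the prefix (dofs 0..k-1 at xv) is shared across components
        prefix = base.copy()
        for k in range(n_dof):
            c = prefix.copy()
            _apply_one(c, flat[k], xv[k] + h)
            _apply_flat(c, flat, xv, start=k + 1)
            stack[k] = c
            _apply_one(prefix, flat[k], xv[k])
        e0 = sf.total_coords(pose, prefix)
        return (sf.total_batch(pose, stack) - e0) / h

    step = 0.1  # initial line-search step, radians; adapted across iterations
    for _ in range(params.min_max_iter):
        grad = gradient(x)
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-9:
            break
        direction = -grad / gnorm
        step = min(step * 2.0, 0.1)
        moved = False
        while step >= params.min_tol:
            trial = x + step * direction
            e_trial = energy(trial)
            if e_trial < e_cur - 1e-12:
                gain = e_cur - e_trial
                x, e_cur, moved = trial, e_trial, True
                break
            step /= 2
        if not moved or gain < params.min_improve:
            break
    final = apply_x(x)
    pose.structure.coords = final[:n_p]
    pose.ligand.coords = final[n_p : n_p + n_l]
    return pose


def run_high_res(
    pose: Pose,
    params: HighResParams = DEFAULT_HIGHRES,
    rng: np.random.Generator | None = None,
    sf: ScoreFunction | None = None,
) -> Pose:
    """Six Metropolis cycles of perturb/repack/minimize, then final
    minimization of the best-seen pose; returns a scored pose."""
    rng = rng if rng is not None else np.random.default_rng(0)
    sf = sf or ScoreFunction()
    current = pose.copy()
    e_cur = sf.total(current)
    best, e_best = current.copy(), e_cur
    for cycle in range(1, params.n_cycles + 1):
        trial = perturb_rigid_body(current, params, rng)
        mode = "repack" if cycle == params.full_repack_cycle else "trials"
        trial = repack_sidechains(trial, mode, params, rng, sf)
        trial = minimize_torsions(trial, "sidechain+ligand", params, sf)
        e_trial = sf.total(trial)
        if metropolis_accept(e_trial - e_cur, params.mc_temperature, rng):
            current, e_cur = trial, e_trial
            if e_cur < e_best:
                best, e_best = current.copy(), e_cur
    final = minimize_torsions(best, "final", params, sf)
    score_pose(final, sf.weights)
    return final
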