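"""Synthetic toy binding pockets and score-table ensembles.

These generators exist so that every stage of the protocol — water
selection, decoy placement, low/high-resolution docking, ranking and
replication statistics — can be exercised end to end without any external
structure.  The geometry is idealized and chemistry-light on purpose: a
hemispherical shell of serine/glycine residues forms a concave site around
a small branched ligand (two hydroxyls, one ketone, three rotatable bonds),
optionally with a bridging water hydrogen-bonded to both partners, placed
so the loose/tight classification holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranking import ModelRecord
from .structure import (
    Atom,
    LigandModel,
    Pose,
    Structure,
    WaterdockError,
    WaterSet,
    assign_atom_types,
)
from .waters import classify_waters


@dataclass
class ToyPocketSpec:
    """Parameters of the synthetic pocket."""

    pocket_radius: float = 6.5  # A, shell radius around the ligand
    n_shell_residues: int = 8
    bridge_water: str | None = "tight"  # None | "loose" | "tight"
    seed: int = 0


def _toy_ligand() -> LigandModel:
    """Small branched ligand: 2 hydroxyls, 1 ketone, 3 rotatable bonds."""
    atoms = [
        Atom("C1", "C", [0.00, 0.00, 0.00]),
        Atom("C2", "C", [1.52, 0.00, 0.00]),
        Atom("O1", "O", [2.00, 1.25, 0.00]),
        Atom("HO1", "H", [2.181, 2.020, -0.543], is_hydrogen=True),
        Atom("C3", "C", [-0.76, 1.32, 0.10]),
        Atom("O2", "O", [-2.10, 1.35, 0.05]),
        Atom("HO2", "H", [-2.45, 2.20, 0.30], is_hydrogen=True),
        Atom("C4", "C", [-0.70, -1.35, -0.10]),
        Atom("O3", "O", [-1.85, -1.83, -0.15]),
        Atom("C5", "C", [0.52, -2.23, -0.20]),
    ]
    names = [a.name for a in atoms]
    ix = {n: i for i, n in enumerate(names)}
    bonds = [
        (ix["C1"], ix["C2"], 1),
        (ix["C2"], ix["O1"], 1),
        (ix["O1"], ix["HO1"], 1),
        (ix["C1"], ix["C3"], 1),
        (ix["C3"], ix["O2"], 1),
        (ix["O2"], ix["HO2"], 1),
        (ix["C1"], ix["C4"], 1),
        (ix["C4"], ix["O3"], 2),
        (ix["C4"], ix["C5"], 1),
    ]
    lig = LigandModel(atoms, bonds)
    assign_atom_types(lig)
    return lig


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


def _serine_residue(og: np.ndarray, outward: np.ndarray, with_hg: bool = True):
    """SER atoms built outward from a given OG position."""
    u = outward / np.linalg.norm(outward)
    t1, _t2 = _orthonormal_frame(u)
    atoms = [
        ("OG", "O", og),
        ("CB", "C", og + 1.43 * u + 0.25 * t1),
        ("CA", "C", og + 2.55 * u + 1.15 * t1),
        ("N", "N", og + 3.10 * u + 2.45 * t1),
        ("C", "C", og + 3.85 * u + 0.55 * t1),
        ("O", "O", og + 5.05 * u + 0.65 * t1),
    ]
    if with_hg:
        atoms.insert(1, ("HG", "H", og - 0.96 * u))
    return atoms


def _glycine_residue(anchor: np.ndarray, outward: np.ndarray):
    u = outward / np.linalg.norm(outward)
    t1, _ = _orthonormal_frame(u)
    return [
        ("CA", "C", anchor),
        ("N", "N", anchor + 1.2 * u + 0.9 * t1),
        ("C", "C", anchor + 1.3 * u - 0.9 * t1),
        ("O", "O", anchor + 2.5 * u - 1.0 * t1),
    ]


def make_toy_pocket(
    spec: ToyPocketSpec = ToyPocketSpec(),
) -> tuple[Structure, LigandModel, WaterSet, Pose]:
    """Build the synthetic pocket; returns (structure, ligand, waters, pose).

    Deterministic under ``spec.seed``.  When ``bridge_water`` is requested,
    the water's loose/tight label is verified against the interface-water
    filter before returning.
    """
    rng = np.random.default_rng(spec.seed)
    ligand = _toy_ligand()
    lig_radius = float(
        np.max(np.linalg.norm(ligand.coords - ligand.centroid, axis=1))
    )
    if spec.pocket_radius <= lig_radius:
        raise WaterdockError(
            f"pocket radius {spec.pocket_radius} must exceed ligand radius "
            f"{lig_radius:.2f}"
        )

    proto_atoms: list[Atom] = []
    chain_ids: list[str] = []
    res_names: list[str] = []
    res_nums: list[int] = []
    resnum = 0

    def add_residue(rname: str, atoms) -> None:
        nonlocal resnum
        resnum += 1
        for name, el, coord in atoms:
            proto_atoms.append(
                Atom(name, el, np.asarray(coord, float), is_hydrogen=(el == "H"))
            )
            chain_ids.append("A")
            res_names.append(rname)
            res_nums.append(resnum)

    # hemispherical shell (cavity opens toward +z), deterministic spiral
    n = spec.n_shell_residues
    for k in range(n):
        phi = np.arccos(-(k + 0.5) / n)  # z < 0 hemisphere
        theta = np.pi * (1 + 5**0.5) * k
        u = np.array(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        u += rng.normal(scale=0.02, size=3)
        u /= np.linalg.norm(u)
        og = (spec.pocket_radius - 1.0) * u
        if k % 3 == 2:
            add_residue("GLY", _glycine_residue(og, u))
        else:
            add_residue("SER", _serine_residue(og, u))

    # bridging water between ligand hydroxyl O1 and one or two anchor serines
    water_oxygens = []
    if spec.bridge_water in ("loose", "tight"):
        o1 = ligand.coords[2]  # O1
        c2 = ligand.coords[1]  # C2, bonded to O1
        e = (c2 - o1) / np.linalg.norm(c2 - o1)
        up = np.array([0.0, 0.0, 1.0])
        up = up - (up @ e) * e
        up /= np.linalg.norm(up)
        # tight: tilt toward C2 so two ligand atoms fall inside 3.0 A;
        # loose: straight up from O1 so only O1 does
        a = 0.20 if spec.bridge_water == "tight" else 0.0
        v = a * e + np.sqrt(1 - a * a) * up
        w = o1 + 2.8 * v
        water_oxygens.append(w)
        u1 = np.array([0.5547, 0.0, 0.8321])
        add_residue("SER", _serine_residue(w + 2.8 * u1, u1))
        if spec.bridge_water == "tight":
            u2 = np.array([-0.430, 0.560, 0.707])
            u2 /= np.linalg.norm(u2)
            add_residue("SER", _serine_residue(w + 2.8 * u2, u2))
    elif spec.bridge_water is not None:
        raise WaterdockError(f"unknown bridge_water mode {spec.bridge_water!r}")

    structure = Structure(proto_atoms, chain_ids, res_names, res_nums)
    assign_atom_types(structure)
    waters = WaterSet(
        np.array(water_oxygens).reshape(-1, 3),
        origins=["crystallographic"] * len(water_oxygens),
        rng=rng,
    )

    if spec.bridge_water in ("loose", "tight"):
        labels = [c.label for c in classify_waters(structure, ligand, waters)]
        if spec.bridge_water == "tight" and labels != ["tight"]:
            raise WaterdockError(f"pocket infeasible: water labeled {labels}")
        if spec.bridge_water == "loose" and labels != ["loose"]:
            raise WaterdockError(f"pocket infeasible: water labeled {labels}")

    pose = Pose(structure, ligand, waters)
    return structure, ligand, waters, pose


def make_model_ensemble(
    native: Pose,
    n_models: int,
    rmsd_profile: np.ndarray | None = None,
    score_noise: float = 1.0,
    seed: int = 0,
) -> tuple[list[ModelRecord], list[Pose]]:
    """Decoy ensemble with planted RMSDs and scores monotone in RMSD.

    Each decoy is a rigid translation of the native ligand by a vector whose
    norm equals the planted RMSD (for a pure translation the two coincide
    exactly), scored as a linear function of RMSD plus seeded Gaussian
    noise, so ranking behavior is predictable.
    """
    rng = np.random.default_rng(seed)
    if rmsd_profile is None:
        rmsd_profile = np.linspace(0.2, 8.0, n_models)
    rmsd_profile = np.asarray(rmsd_profile, float)
    if len(rmsd_profile) != n_models:
        raise WaterdockError("rmsd_profile length must equal n_models")
    records: list[ModelRecord] = []
    poses: list[Pose] = []
    for m in range(n_models):
        r = float(rmsd_profile[m])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pose = native.copy()
        pose.ligand.coords = pose.ligand.coords + r * direction
        total = -50.0 + 3.0 * r + rng.normal(scale=score_noise)
        interface = -20.0 + 2.0 * r + rng.normal(scale=score_noise)
        records.append(
            ModelRecord(
                model_id=m,
                total_score=total,
                interface_ligand=interface,
                ligand_rmsd=r,
            )
        )
        poses.append(pose)
    return records, poses
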