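"""Interface-water classification and binding-site crowdedness.

A crystallographic water is a *loose* interface water when its oxygen lies
within 3.0 A of at least one protein atom and one ligand atom, and *tight*
when within 3.0 A of at least two of each.  Crowdedness is the number of
predicted protein/ligand polar contacts divided by the number of ligand
heavy atoms; sites below a crowdedness of ~2 are the ones water docking
tends to help.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import LigandModel, Structure, WaterdockError, WaterSet

DEFAULT_WATER_CUTOFF = 3.0  # A, water-O to partner-atom distance
DEFAULT_CENTER_CUTOFF = 3.6  # A, polar-contact distance for exposed atoms
DEFAULT_EDGE_CUTOFF = 3.2  # A, polar-contact distance for buried atoms
CROWDEDNESS_THRESHOLD = 2.0  # contacts per ligand heavy atom (reporting only)

_DONOR_ROLES = ("donor-heavy", "both")
_ACCEPTOR_ROLES = ("acceptor", "both")


@dataclass
class WaterClass:
    """Contact counts and loose/tight label for one water."""

    index: int
    n_protein_contacts: int
    n_ligand_contacts: int
    label: str  # loose | tight | none


@dataclass
class CrowdednessReport:
    n_polar_contacts: int
    n_ligand_atoms: int
    crowdedness: float


def classify_waters(
    structure: Structure,
    ligand: LigandModel,
    waters: WaterSet,
    cutoff: float = DEFAULT_WATER_CUTOFF,
) -> list[WaterClass]:
    """Per-water protein/ligand contact counts and loose/tight/none labels.

    Distances are measured from the water oxygen to every atom present in
    the input (hydrogens included if present, matching crystallographic
    practice where they usually are not).
    """
    if cutoff <= 0:
        raise WaterdockError("cutoff must be positive")
    out: list[WaterClass] = []
    if len(waters) == 0:
        return out
    dp = cdist(waters.oxygens, structure.coords)
    dl = cdist(waters.oxygens, ligand.coords)
    for w in range(len(waters)):
        np_c = int((dp[w] <= cutoff).sum())
        nl_c = int((dl[w] <= cutoff).sum())
        if np_c >= 2 and nl_c >= 2:
            label = "tight"
        elif np_c >= 1 and nl_c >= 1:
            label = "loose"
        else:
            label = "none"
        out.append(WaterClass(w, np_c, nl_c, label))
    return out


def select_interface_waters(
    structure: Structure,
    ligand: LigandModel,
    waters: WaterSet,
    mode: str = "loose",
    cutoff: float = DEFAULT_WATER_CUTOFF,
) -> tuple[WaterSet, list[WaterClass]]:
    """Subset of waters passing the loose or tight filter, in input order."""
    if mode not in ("loose", "tight"):
        raise WaterdockError(f"unknown water selection mode {mode!r}")
    classes = classify_waters(structure, ligand, waters, cutoff)
    wanted = ("loose", "tight") if mode == "loose" else ("tight",)
    idx = [c.index for c in classes if c.label in wanted]
    return waters.subset(idx), classes


def _heavy_neighbor_counts(
    coords: np.ndarray, heavy: np.ndarray, bond_cut: float = 1.8
) -> np.ndarray:
    """Heavy neighbors within covalent distance, used as a burial proxy."""
    n = len(coords)
    if n == 0:
        return np.zeros(0, dtype=int)
    d = cdist(coords, coords)
    near = (d > 1e-6) & (d <= bond_cut)
    near[:, ~heavy] = False
    return near.sum(axis=1)


def polar_contacts(
    structure: Structure,
    ligand: LigandModel,
    waters: WaterSet | None = None,
    center_cutoff: float = DEFAULT_CENTER_CUTOFF,
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Donor/acceptor heavy-atom contact pairs between protein and ligand(+waters).

    A contact pairs a donor-capable atom with an acceptor-capable atom, one
    from the protein and one from the ligand or a water, at heavy-atom
    distance <= ``center_cutoff`` — tightened to ``edge_cutoff`` when either
    atom has three or more covalently attached heavy neighbors (a buriedness
    proxy standing in for PyMOL's unpublished edge criterion).  Each
    unordered pair is reported once as ((side, index), (side, index)).
    """
    p_heavy = structure.heavy_mask
    p_idx = np.where(p_heavy)[0]
    p_roles = [structure.roles[i] for i in p_idx]
    p_coords = structure.coords[p_idx]
    p_nbrs = _heavy_neighbor_counts(structure.coords, p_heavy)[p_idx]

    l_heavy = ligand.heavy_mask
    l_idx = np.where(l_heavy)[0]
    l_roles = [ligand.roles[i] for i in l_idx]
    l_coords = ligand.coords[l_idx]
    l_nbrs = _heavy_neighbor_counts(ligand.coords, l_heavy)[l_idx]

    sides = [("ligand", int(i), r, c, int(nb))
             for i, r, c, nb in zip(l_idx, l_roles, l_coords, l_nbrs)]
    if waters is not None and len(waters):
        for w in range(len(waters)):
            sides.append(("water", w, "both", waters.oxygens[w], 0))

    contacts = []
    for pi, pr, pc, pnb in zip(p_idx, p_roles, p_coords, p_nbrs):
        if pr == "none":
            continue
        for side, si, sr, sc, snb in sides:
            if sr == "none":
                continue
            donor_ok = (pr in _DONOR_ROLES and sr in _ACCEPTOR_ROLES) or (
                sr in _DONOR_ROLES and pr in _ACCEPTOR_ROLES
            )
            if not donor_ok:
                continue
            d = float(np.linalg.norm(pc - sc))
            cut = edge_cutoff if (pnb >= 3 or snb >= 3) else center_cutoff
            if d <= cut:
                contacts.append((("protein", int(pi)), (side, si)))
    return contacts


def crowdedness(
    structure: Structure,
    ligand: LigandModel,
    waters: WaterSet | None = None,
    center_cutoff: float = DEFAULT_CENTER_CUTOFF,
    edge_cutoff: float = DEFAULT_EDGE_CUTOFF,
) -> CrowdednessReport:
    """Polar contacts per ligand heavy atom."""
    n_lig = int(ligand.heavy_mask.sum())
    if n_lig == 0:
        raise WaterdockError("crowdedness undefined for an empty ligand")
    contacts = polar_contacts(structure, ligand, waters, center_cutoff, edge_cutoff)
    return CrowdednessReport(
        n_polar_contacts=len(contacts),
        n_ligand_atoms=n_lig,
        crowdedness=len(contacts) / n_lig,
    )
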