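"""Grid-based placement of candidate ("decoy") waters around ligand polar atoms.

For every ligand hydrogen-bond donor or acceptor, a candidate water oxygen is
placed at hydrogen-bonding distance using an XYZ grid: grid points inside any
ligand atom's van der Waals sphere are marked occupied, the spherical shell
between 2.75 and 2.9 A of the polar atom is collected, occupied points are
removed, and the surviving point with the shortest average distance to the
rest of its own set becomes the water coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .structure import LigandModel, Structure, WaterdockError, WaterSet

WATER_OXYGEN_RADIUS = 1.52  # A, used for protein-clash screening


@dataclass(frozen=True)
class ShellSpec:
    """Hydrogen-bonding shell radii around a polar atom."""

    inner: float = 2.75
    outer: float = 2.90

    def __post_init__(self) -> None:
        if not (0 < self.inner < self.outer):
            raise WaterdockError("shell requires 0 < inner < outer")


DEFAULT_SHELL = ShellSpec()
DEFAULT_SPACING = 0.15  # A
GRID_MARGIN = 4.0  # A beyond the ligand bounding box


def place_decoy_waters(
    ligand: LigandModel,
    shell: ShellSpec = DEFAULT_SHELL,
    spacing: float = DEFAULT_SPACING,
    rng: np.random.Generator | None = None,
) -> WaterSet:
    """One candidate water per ligand donor/acceptor whose shell survives
    the occupancy filter; returns them as decoy-tagged waters.

    Ligands with no polar atoms yield an empty set.  Each returned oxygen is
    a grid point whose distance to its parent atom lies in
    ``[shell.inner, shell.outer]`` and which is outside the van der Waals
    sphere of every ligand atom.
    """
    if spacing <= 0:
        raise WaterdockError("grid spacing must be positive")
    # a spacing equal to the shell width still yields points (grid diagonals
    # are shorter than the axis spacing); only strictly coarser grids fail
    if spacing > shell.outer - shell.inner + 1e-9:
        raise WaterdockError("grid too coarse")

    polar = [
        i
        for i in range(len(ligand))
        if ligand.roles[i] in ("donor-heavy", "acceptor", "both")
        and not ligand.is_hydrogen[i]
    ]
    if not polar:
        return WaterSet(rng=rng)

    # translate ligand to the grid origin (bounding box minus margin at 0)
    lo = ligand.coords.min(axis=0) - GRID_MARGIN
    hi = ligand.coords.max(axis=0) + GRID_MARGIN
    shifted = ligand.coords - lo

    oxygens: list[np.ndarray] = []
    for i in polar:
        pts = _shell_grid_points(shifted[i], shell, spacing, hi - lo)
        if len(pts) == 0:
            continue
        # occupancy: drop points inside any ligand atom's own vdW sphere
        d = cdist(pts, shifted)
        free = np.all(d >= ligand.vdw[None, :], axis=1)
        pts = pts[free]
        if len(pts) == 0:
            continue
        center = _central_point(pts)
        oxygens.append(center + lo)

    if not oxygens:
        return WaterSet(rng=rng)
    return WaterSet(
        np.array(oxygens),
        origins=["decoy"] * len(oxygens),
        rng=rng,
    )


def _shell_grid_points(
    center: np.ndarray, shell: ShellSpec, spacing: float, bounds: np.ndarray
) -> np.ndarray:
    """Grid points (multiples of ``spacing`` from the origin) whose distance
    to ``center`` lies within the shell, clipped to the grid bounds."""
    lo_idx = np.maximum(np.floor((center - shell.outer) / spacing).astype(int), 0)
    hi_idx = np.minimum(
        np.ceil((center + shell.outer) / spacing).astype(int),
        np.floor(bounds / spacing).astype(int),
    )
    axes = [np.arange(lo_idx[k], hi_idx[k] + 1) * spacing for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d = np.linalg.norm(pts - center, axis=1)
    return pts[(d >= shell.inner) & (d <= shell.outer)]


def _central_point(pts: np.ndarray) -> np.ndarray:
    """The point with the shortest average distance to all other points;
    ties broken by lowest (x, y, z) lexicographic order."""
    n = len(pts)
    if n == 1:
        return pts[0]
    sums = np.zeros(n)
    chunk = 512  # bound the distance-matrix memory footprint
    for s in range(0, n, chunk):
        sums[s : s + chunk] = cdist(pts[s : s + chunk], pts).sum(axis=1)
    best = np.min(sums)
    cand = np.where(sums <= best + 1e-9)[0]
    order = np.lexsort((pts[cand, 2], pts[cand, 1], pts[cand, 0]))
    return pts[cand[order[0]]]


def choose_random_decoy(
    decoys: WaterSet,
    structure: Structure,
    rng: np.random.Generator,
) -> WaterSet:
    """Pick one non-protein-clashing decoy water uniformly at random.

    A decoy clashes when any protein heavy atom lies within the sum of the
    water-oxygen and protein-atom vdW radii of its oxygen.
    """
    if len(decoys) == 0:
        raise WaterdockError("no decoy candidates")
    heavy = structure.heavy_mask
    pcoords = structure.coords[heavy]
    pradii = structure.vdw[heavy]
    ok = []
    for w in range(len(decoys)):
        d = np.linalg.norm(pcoords - decoys.oxygens[w], axis=1)
        if np.all(d >= WATER_OXYGEN_RADIUS + pradii):
            ok.append(w)
    if not ok:
        raise WaterdockError("no placeable decoy")
    choice = ok[int(rng.integers(len(ok)))]
    return decoys.subset([choice])
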