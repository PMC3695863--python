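"""PDB-backed molecular data model.

Reads protein/ligand/water complexes from standard PDB text, normalizes
naming (protein chains relabeled alphabetically, ligand on chain ``X`` as
residue ``INH``, waters on chain ``W`` as residue ``WAT``), assigns van der
Waals radii and hydrogen-bond roles, and computes ligand descriptors.

Containers are array-backed: coordinates live in an ``(N, 3)`` float array so
rigid-body moves and scoring are vectorized; :class:`Atom` is the per-atom
record view used for construction and inspection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import WATER_HOH_ANGLE, WATER_OH_LENGTH, build_water_hydrogens

__all__ = [
    "Atom",
    "AtomArray",
    "Structure",
    "LigandModel",
    "LigandTopology",
    "WaterSet",
    "LigandDescriptors",
    "Pose",
    "read_complex",
    "assign_atom_types",
    "ligand_descriptors",
    "write_model",
    "parse_params_table",
    "WaterdockError",
    "LigandMissingError",
    "ConnectivityError",
    "UnknownElementError",
]


class WaterdockError(Exception):
    """Base class for package errors."""


class LigandMissingError(WaterdockError):
    pass


class ConnectivityError(WaterdockError):
    pass


class UnknownElementError(WaterdockError):
    pass


# Bondi-style van der Waals radii (Angstrom), element-keyed.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}

WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"}
CAP_RESNAMES = {"ACE", "NME", "NMA"}

CANONICAL_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Common non-canonical residues mapped to their canonical parent.
NONCANONICAL_MAP = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "HYP": "PRO", "MLY": "LYS", "M3L": "LYS", "CME": "CYS", "KCX": "LYS",
    "HIE": "HIS", "HID": "HIS", "HIP": "HIS", "CYX": "CYS",
}

# Hydrogen-bond roles for protein atoms, keyed by (residue, atom name).
# Backbone N/O handled generically.
_SIDECHAIN_ROLES = {
    ("SER", "OG"): "both", ("THR", "OG1"): "both", ("TYR", "OH"): "both",
    ("ASN", "OD1"): "acceptor", ("ASN", "ND2"): "donor-heavy",
    ("GLN", "OE1"): "acceptor", ("GLN", "NE2"): "donor-heavy",
    ("ASP", "OD1"): "acceptor", ("ASP", "OD2"): "acceptor",
    ("GLU", "OE1"): "acceptor", ("GLU", "OE2"): "acceptor",
    ("LYS", "NZ"): "donor-heavy",
    ("ARG", "NE"): "donor-heavy", ("ARG", "NH1"): "donor-heavy",
    ("ARG", "NH2"): "donor-heavy",
    ("HIS", "ND1"): "both", ("HIS", "NE2"): "both",
    ("TRP", "NE1"): "donor-heavy",
}


@dataclass
class Atom:
    """One atom: label, element, coordinate, typing annotations."""

    name: str
    element: str
    coord: np.ndarray
    is_hydrogen: bool = False
    vdw_radius: float = 0.0
    hbond_role: str = "none"
    partial_charge: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise WaterdockError(f"non-finite coordinate for atom {self.name}")


class AtomArray:
    """Array-backed atom container; base for Structure and LigandModel."""

    def __init__(self, atoms: list[Atom]):
        self.names: list[str] = [a.name for a in atoms]
        self.elements: list[str] = [a.element.upper() for a in atoms]
        self.coords: np.ndarray = (
            np.array([a.coord for a in atoms], dtype=float).reshape(len(atoms), 3)
        )
        self.is_hydrogen: np.ndarray = np.array(
            [a.is_hydrogen for a in atoms], dtype=bool
        )
        self.vdw: np.ndarray = np.array([a.vdw_radius for a in atoms], dtype=float)
        self.roles: list[str] = [a.hbond_role for a in atoms]
        self.charges: np.ndarray = np.array(
            [a.partial_charge for a in atoms], dtype=float
        )

    def __len__(self) -> int:
        return len(self.names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return ~self.is_hydrogen

    def atom(self, i: int) -> Atom:
        return Atom(
            name=self.names[i],
            element=self.elements[i],
            coord=self.coords[i].copy(),
            is_hydrogen=bool(self.is_hydrogen[i]),
            vdw_radius=float(self.vdw[i]),
            hbond_role=self.roles[i],
            partial_charge=float(self.charges[i]),
        )

    def _copy_onto(self, new: "AtomArray") -> None:
        new.names = list(self.names)
        new.elements = list(self.elements)
        new.coords = self.coords.copy()
        new.is_hydrogen = self.is_hydrogen.copy()
        new.vdw = self.vdw.copy()
        new.roles = list(self.roles)
        new.charges = self.charges.copy()


class Structure(AtomArray):
    """Protein structure with chain/residue organization over a flat atom list."""

    def __init__(
        self,
        atoms: list[Atom],
        chain_ids: list[str],
        res_names: list[str],
        res_nums: list[int],
    ):
        super().__init__(atoms)
        if not (len(chain_ids) == len(res_names) == len(res_nums) == len(atoms)):
            raise WaterdockError("per-atom residue annotation length mismatch")
        self.chain_ids = list(chain_ids)
        self.res_names = list(res_names)
        self.res_nums = list(res_nums)
        self._rebuild_residue_index()

    def _rebuild_residue_index(self) -> None:
        self.residue_index: dict[tuple[str, int], np.ndarray] = {}
        order: list[tuple[str, int]] = []
        buckets: dict[tuple[str, int], list[int]] = {}
        for i, (c, n) in enumerate(zip(self.chain_ids, self.res_nums)):
            key = (c, n)
            if key not in buckets:
                buckets[key] = []
                order.append(key)
            buckets[key].append(i)
        for key in order:
            self.residue_index[key] = np.array(buckets[key], dtype=int)
        self._residue_order = order

    def residues(self):
        """Yield (chain, resnum, resname, atom index array) in file order."""
        for chain, num in self._residue_order:
            idx = self.residue_index[(chain, num)]
            yield chain, num, self.res_names[idx[0]], idx

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        for i in self.residue_index[(chain, resnum)]:
            if self.names[i] == name:
                return int(i)
        raise KeyError(f"atom {name} not in residue {chain}{resnum}")

    def copy(self) -> "Structure":
        new = object.__new__(Structure)
        self._copy_onto(new)
        new.chain_ids = list(self.chain_ids)
        new.res_names = list(self.res_names)
        new.res_nums = list(self.res_nums)
        new.residue_index = {k: v.copy() for k, v in self.residue_index.items()}
        new._residue_order = list(self._residue_order)
        return new


@dataclass
class LigandTopology:
    """Ligand connectivity: names, elements, bonds with order, optional roles."""

    names: list[str]
    elements: list[str]
    bonds: list[tuple[int, int, int]]  # (i, j, order)
    roles: dict[str, str] = field(default_factory=dict)


class LigandModel(AtomArray):
    """Small-molecule ligand: atoms, bond graph, rotatable torsions."""

    def __init__(
        self,
        atoms: list[Atom],
        bonds: list[tuple[int, int, int]],
        rotatable_torsions: list[tuple[int, int, int, int]] | None = None,
    ):
        super().__init__(atoms)
        self.bonds = [(int(i), int(j), int(o)) for i, j, o in bonds]
        for i, j, _ in self.bonds:
            if not (0 <= i < len(self) and 0 <= j < len(self)):
                raise ConnectivityError(f"bond ({i},{j}) references missing atom")
        self._check_connected()
        if rotatable_torsions is None:
            rotatable_torsions = _find_rotatable_torsions(self)
        self.rotatable_torsions = [tuple(int(x) for x in t) for t in rotatable_torsions]

    def _check_connected(self) -> None:
        if len(self) <= 1:
            return
        adj = self.neighbors()
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != len(self):
            raise ConnectivityError("ligand bond graph is not connected")

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(len(self))]
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    @property
    def centroid(self) -> np.ndarray:
        """Mean of heavy-atom coordinates (recomputed on access)."""
        return self.coords[self.heavy_mask].mean(axis=0)

    def copy(self) -> "LigandModel":
        new = object.__new__(LigandModel)
        self._copy_onto(new)
        new.bonds = list(self.bonds)
        new.rotatable_torsions = list(self.rotatable_torsions)
        return new


def _bond_in_ring(n_atoms: int, bonds: list[tuple[int, int, int]], bi: int) -> bool:
    """A bond is in a ring iff removing it keeps its endpoints connected."""
    i0, j0, _ = bonds[bi]
    adj: dict[int, list[int]] = {k: [] for k in range(n_atoms)}
    for b, (i, j, _) in enumerate(bonds):
        if b == bi:
            continue
        adj[i].append(j)
        adj[j].append(i)
    seen = {i0}
    stack = [i0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb == j0:
                return True
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return False


def _find_rotatable_torsions(lig: LigandModel) -> list[tuple[int, int, int, int]]:
    """Rotatable bond: single, non-ring, non-terminal, with at least one heavy
    substituent on each side; returns one 4-atom torsion per such bond."""
    adj = lig.neighbors()
    heavy = lig.heavy_mask
    torsions = []
    for bi, (j, k, order) in enumerate(lig.bonds):
        if order != 1:
            continue
        if lig.is_hydrogen[j] or lig.is_hydrogen[k]:
            continue
        heavy_j = [n for n in adj[j] if n != k and heavy[n]]
        heavy_k = [n for n in adj[k] if n != j and heavy[n]]
        if not heavy_j or not heavy_k:
            continue  # terminal bond
        if _bond_in_ring(len(lig), lig.bonds, bi):
            continue
        torsions.append((min(heavy_j), j, k, min(heavy_k)))
    return torsions


class WaterSet:
    """Ordered collection of waters, each an oxygen plus two rigid hydrogens.

    Hydrogens are constructed at rigid water geometry (O-H 0.9572 A,
    H-O-H 104.52 deg) when absent from the input.
    """

    def __init__(
        self,
        oxygens: np.ndarray | None = None,
        hydrogens: np.ndarray | None = None,
        origins: list[str] | None = None,
        rng: np.random.Generator | None = None,
    ):
        if oxygens is None:
            oxygens = np.zeros((0, 3))
        self.oxygens = np.asarray(oxygens, dtype=float).reshape(-1, 3)
        n = len(self.oxygens)
        self.origins = list(origins) if origins is not None else ["crystallographic"] * n
        if hydrogens is None:
            rng = rng if rng is not None else np.random.default_rng(0)
            hyd = np.zeros((n, 2, 3))
            for w in range(n):
                h1, h2 = build_water_hydrogens(self.oxygens[w], rng)
                hyd[w, 0], hyd[w, 1] = h1, h2
            self.hydrogens = hyd
        else:
            self.hydrogens = np.asarray(hydrogens, dtype=float).reshape(n, 2, 3)
        if len(self.origins) != n:
            raise WaterdockError("water origin tags length mismatch")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        for w in range(len(self)):
            for h in range(2):
                d = np.linalg.norm(self.hydrogens[w, h] - self.oxygens[w])
                if abs(d - WATER_OH_LENGTH) > 1e-6:
                    raise WaterdockError(f"water {w}: O-H length {d:.4f}")
            v1 = self.hydrogens[w, 0] - self.oxygens[w]
            v2 = self.hydrogens[w, 1] - self.oxygens[w]
            c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
            if abs(ang - WATER_HOH_ANGLE) > 1e-4:
                raise WaterdockError(f"water {w}: H-O-H angle {ang:.3f}")

    def __len__(self) -> int:
        return len(self.oxygens)

    def subset(self, indices) -> "WaterSet":
        idx = np.asarray(indices, dtype=int)
        return WaterSet(
            self.oxygens[idx],
            self.hydrogens[idx],
            [self.origins[i] for i in idx],
        )

    def copy(self) -> "WaterSet":
        return WaterSet(
            self.oxygens.copy(), self.hydrogens.copy(), list(self.origins)
        )


@dataclass
class LigandDescriptors:
    """Counts used to characterize a docking input's ligand."""

    n_atoms: int
    mol_weight: float
    n_rotatable: int
    n_hbd: int
    n_hba: int


@dataclass
class Pose:
    """One docking state: protein + ligand + waters (+ score breakdown)."""

    structure: Structure
    ligand: LigandModel
    waters: WaterSet
    scores: object | None = None
    strained: bool = False

    def copy(self) -> "Pose":
        return Pose(
            self.structure.copy(),
            self.ligand.copy(),
            self.waters.copy(),
            self.scores,
            self.strained,
        )


# ---------------------------------------------------------------------------
# connectivity input


def parse_params_table(text: str) -> LigandTopology:
    """Parse the internal whitespace-delimited ligand connectivity table.

    One atom per line: ``name element partner[,partner...] [role]`` where a
    partner may carry a bond order suffix ``:2``/``:3`` (default single) and
    role is one of donor/acceptor/both/none.  Lines starting with ``#`` are
    comments.
    """
    names: list[str] = []
    elements: list[str] = []
    partner_specs: list[list[str]] = []
    roles: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ConnectivityError(f"bad params line: {line!r}")
        name, element, partners = fields[0], fields[1], fields[2]
        names.append(name)
        elements.append(element.upper())
        partner_specs.append(partners.split(",") if partners != "-" else [])
        if len(fields) >= 4:
            role = fields[3]
            if role == "donor":
                role = "donor-heavy"
            roles[name] = role
    index = {n: i for i, n in enumerate(names)}
    bonds: set[tuple[int, int, int]] = set()
    for i, specs in enumerate(partner_specs):
        for spec in specs:
            order = 1
            if ":" in spec:
                spec, o = spec.split(":")
                order = int(o)
            if spec not in index:
                raise ConnectivityError(f"connectivity mismatch: unknown atom {spec}")
            j = index[spec]
            bonds.add((min(i, j), max(i, j), order))
    return LigandTopology(names, elements, sorted(bonds), roles)


def topology_from_molblock(molblock: str) -> LigandTopology:
    """Build a LigandTopology from an SDF/MOL bond block (requires rdkit)."""
    from rdkit import Chem  # local import: optional dependency

    mol = Chem.MolFromMolBlock(molblock, removeHs=False, sanitize=False)
    if mol is None:
        raise ConnectivityError("unparsable MOL block")
    names = []
    elements = []
    counts: dict[str, int] = {}
    for a in mol.GetAtoms():
        el = a.GetSymbol()
        counts[el] = counts.get(el, 0) + 1
        names.append(f"{el.upper()}{counts[el]}")
        elements.append(el.upper())
    bonds = []
    for b in mol.GetBonds():
        order = int(b.GetBondTypeAsDouble()) or 1
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append((min(i, j), max(i, j), order))
    return LigandTopology(names, elements, sorted(bonds))


def _infer_bonds_by_distance(
    names: list[str], elements: list[str], coords: np.ndarray
) -> list[tuple[int, int, int]]:
    """Distance-heuristic single bonds for ligands with no connectivity table."""
    covalent = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
                "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39}
    bonds = []
    n = len(names)
    for i in range(n):
        for j in range(i + 1, n):
            ri = covalent.get(elements[i], 0.77)
            rj = covalent.get(elements[j], 0.77)
            if np.linalg.norm(coords[i] - coords[j]) <= 1.25 * (ri + rj):
                bonds.append((i, j, 1))
    return bonds


# ---------------------------------------------------------------------------
# reading


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip().upper()
    if el and el != "X":
        return el
    # fall back on the first alphabetic character of the atom name
    for ch in atom.name:
        if ch.isalpha():
            return ch.upper()
    raise UnknownElementError(f"cannot infer element for atom {atom.name!r}")


def _filter_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name, first on tie."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:
            best[at.name] = at
    # preserve file order
    seen = set()
    out = []
    for at in residue:
        if at.name not in seen and best[at.name] is at:
            out.append(at)
            seen.add(at.name)
        elif at.name not in seen and best[at.name] is not at:
            out.append(best[at.name])
            seen.add(at.name)
    return out


def read_complex(
    pdb_text: str,
    ligand_connectivity: LigandTopology | str | None = None,
    seed: int = 0,
) -> tuple[Structure, LigandModel, WaterSet]:
    """Read a protein/ligand/water complex from PDB text and normalize it.

    Protein chains are relabeled alphabetically in order of appearance, the
    ligand is normalized to chain ``X`` residue ``INH`` and waters to chain
    ``W`` residue ``WAT``.  ACE/NME terminal caps are stripped.  Water
    hydrogens are constructed (seeded orientation) when absent.

    Parameters
    ----------
    ligand_connectivity
        A :class:`LigandTopology`, params-table text, or None (bonds inferred
        from interatomic distances).
    """
    if isinstance(ligand_connectivity, str):
        ligand_connectivity = parse_params_table(ligand_connectivity)

    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise WaterdockError("no model in PDB input")
    model = st[0]

    protein_atoms: list[Atom] = []
    chain_ids: list[str] = []
    res_names: list[str] = []
    res_nums: list[int] = []
    chain_map: dict[str, str] = {}
    water_oxygens: list[np.ndarray] = []
    water_h: list[list[np.ndarray]] = []
    ligand_candidates: list[tuple[str, gemmi.Residue]] = []

    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname in WATER_RESNAMES:
                atoms = _filter_altlocs(res)
                o = [a for a in atoms if _element_of(a) == "O"]
                h = [a for a in atoms if _element_of(a) == "H"]
                for oat in o:
                    water_oxygens.append(np.array(oat.pos.tolist()))
                    water_h.append([np.array(x.pos.tolist()) for x in h[:2]])
                continue
            canonical = NONCANONICAL_MAP.get(rname, rname)
            if canonical in CANONICAL_AA:
                if chain.name not in chain_map:
                    chain_map[chain.name] = chr(ord("A") + len(chain_map))
                new_chain = chain_map[chain.name]
                for at in _filter_altlocs(res):
                    el = _element_of(at)
                    protein_atoms.append(
                        Atom(
                            name=at.name,
                            element=el,
                            coord=np.array(at.pos.tolist()),
                            is_hydrogen=(el == "H"),
                        )
                    )
                    chain_ids.append(new_chain)
                    res_names.append(canonical)
                    res_nums.append(res.seqid.num)
            elif rname in CAP_RESNAMES:
                continue  # strip neutralizing caps
            else:
                ligand_candidates.append((chain.name, res))

    if not ligand_candidates:
        raise LigandMissingError("no ligand found")
    # ligand = largest non-water het residue by heavy atom count
    def _heavy_count(item):
        return sum(1 for a in item[1] if _element_of(a) != "H")

    ligand_candidates.sort(key=_heavy_count, reverse=True)
    lig_res = ligand_candidates[0][1]
    lig_atoms_gemmi = _filter_altlocs(lig_res)
    lig_names = [a.name for a in lig_atoms_gemmi]
    lig_elements = [_element_of(a) for a in lig_atoms_gemmi]
    lig_coords = np.array([a.pos.tolist() for a in lig_atoms_gemmi])

    if ligand_connectivity is not None:
        index = {n: i for i, n in enumerate(lig_names)}
        missing = [n for n in ligand_connectivity.names if n not in index]
        if missing:
            raise ConnectivityError(
                f"connectivity mismatch: atoms {missing} absent from PDB ligand"
            )
        # reorder bonds into PDB atom order
        bonds = [
            (
                index[ligand_connectivity.names[i]],
                index[ligand_connectivity.names[j]],
                o,
            )
            for i, j, o in ligand_connectivity.bonds
        ]
        bonds = [(min(i, j), max(i, j), o) for i, j, o in bonds]
        roles = ligand_connectivity.roles
    else:
        bonds = _infer_bonds_by_distance(lig_names, lig_elements, lig_coords)
        roles = {}

    lig_atom_objs = [
        Atom(
            name=n,
            element=e,
            coord=c,
            is_hydrogen=(e == "H"),
            hbond_role=roles.get(n, "none"),
        )
        for n, e, c in zip(lig_names, lig_elements, lig_coords)
    ]
    ligand = LigandModel(lig_atom_objs, bonds)

    structure = Structure(protein_atoms, chain_ids, res_names, res_nums)

    rng = np.random.default_rng(seed)
    n_w = len(water_oxygens)
    hydrogens = None
    if n_w:
        hydrogens = np.zeros((n_w, 2, 3))
        for w in range(n_w):
            if len(water_h[w]) == 2:
                hydrogens[w, 0], hydrogens[w, 1] = water_h[w]
                # re-idealize if file geometry is off the rigid model
                if not _water_geometry_ok(water_oxygens[w], hydrogens[w]):
                    h1, h2 = build_water_hydrogens(water_oxygens[w], rng)
                    hydrogens[w, 0], hydrogens[w, 1] = h1, h2
            else:
                h1, h2 = build_water_hydrogens(water_oxygens[w], rng)
                hydrogens[w, 0], hydrogens[w, 1] = h1, h2
    waters = WaterSet(
        np.array(water_oxygens).reshape(-1, 3),
        hydrogens,
        ["crystallographic"] * n_w,
    )

    assign_atom_types(structure)
    assign_atom_types(ligand, roles=roles)
    return structure, ligand, waters


def _water_geometry_ok(oxygen: np.ndarray, hyd: np.ndarray) -> bool:
    for h in range(2):
        if abs(np.linalg.norm(hyd[h] - oxygen) - WATER_OH_LENGTH) > 1e-6:
            return False
    v1, v2 = hyd[0] - oxygen, hyd[1] - oxygen
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return abs(np.degrees(np.arccos(np.clip(c, -1, 1))) - WATER_HOH_ANGLE) <= 1e-4


# ---------------------------------------------------------------------------
# typing


def assign_atom_types(obj, roles: dict[str, str] | None = None):
    """Assign vdW radii and hydrogen-bond roles in place; returns the object.

    Protein roles come from backbone/side-chain rules; ligand roles from the
    connectivity table when provided, otherwise inferred from element and
    attached hydrogens (O-H -> both, bare O -> acceptor, N-H -> donor,
    bare N -> acceptor).
    """
    for i, el in enumerate(obj.elements):
        if el not in VDW_RADII:
            raise UnknownElementError(
                f"unknown element {el!r} for atom {obj.names[i]}"
            )
        obj.vdw[i] = VDW_RADII[el]

    if isinstance(obj, Structure):
        _assign_protein_roles(obj)
    elif isinstance(obj, LigandModel):
        _assign_ligand_roles(obj, roles or {})
    return obj


def _assign_protein_roles(st: Structure) -> None:
    for i, name in enumerate(st.names):
        el = st.elements[i]
        if el == "H":
            st.roles[i] = "none"
            continue
        res = st.res_names[i]
        if name == "N":
            st.roles[i] = "none" if res == "PRO" else "donor-heavy"
        elif name in ("O", "OXT"):
            st.roles[i] = "acceptor"
        elif (res, name) in _SIDECHAIN_ROLES:
            st.roles[i] = _SIDECHAIN_ROLES[(res, name)]
        elif el == "O":
            st.roles[i] = "acceptor"
        elif el == "N":
            st.roles[i] = "donor-heavy"
        else:
            st.roles[i] = "none"


def _assign_ligand_roles(lig: LigandModel, roles: dict[str, str]) -> None:
    adj = lig.neighbors()
    for i, el in enumerate(lig.elements):
        if lig.names[i] in roles:
            lig.roles[i] = roles[lig.names[i]]
            continue
        if el == "H":
            lig.roles[i] = "none"
            continue
        has_h = any(lig.is_hydrogen[n] for n in adj[i])
        if el == "O":
            lig.roles[i] = "both" if has_h else "acceptor"
        elif el == "N":
            lig.roles[i] = "donor-heavy" if has_h else "acceptor"
        else:
            lig.roles[i] = "none"


def ligand_descriptors(ligand: LigandModel) -> LigandDescriptors:
    """Atom count, molecular weight, rotatable-bond and H-bond donor/acceptor
    counts for a typed ligand."""
    mw = sum(ATOMIC_MASS.get(el, 0.0) for el in ligand.elements)
    n_hbd = sum(1 for r in ligand.roles if r in ("donor-heavy", "both"))
    n_hba = sum(1 for r in ligand.roles if r in ("acceptor", "both"))
    return LigandDescriptors(
        n_atoms=len(ligand),
        mol_weight=mw,
        n_rotatable=len(ligand.rotatable_torsions),
        n_hbd=n_hbd,
        n_hba=n_hba,
    )


# ---------------------------------------------------------------------------
# writing


def write_model(pose: Pose, destination=None) -> str:
    """Write a pose as PDB text (protein chains, ligand X/INH, waters W/WAT).

    Returns the PDB string; also writes it to ``destination`` (path or
    file-like) when given.  Round-trips through :func:`read_complex` with
    coordinates equal to three decimals.
    """
    for arr in (pose.structure.coords, pose.ligand.coords, pose.waters.oxygens):
        if arr.size and (np.abs(arr).max() >= 10000.0 or np.min(arr) <= -1000.0):
            raise WaterdockError("coordinate overflows fixed PDB columns")

    st = gemmi.Structure()
    model = gemmi.Model("1")

    for chain_id in sorted(set(pose.structure.chain_ids)):
        chain = gemmi.Chain(chain_id)
        for c, num, rname, idx in pose.structure.residues():
            if c != chain_id:
                continue
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(int(num), " ")
            res.het_flag = "A"
            for i in idx:
                res.add_atom(_gemmi_atom(pose.structure, int(i)))
            chain.add_residue(res)
        model.add_chain(chain)

    lig_chain = gemmi.Chain("X")
    lig_res = gemmi.Residue()
    lig_res.name = "INH"
    lig_res.seqid = gemmi.SeqId(1, " ")
    lig_res.het_flag = "H"
    for i in range(len(pose.ligand)):
        lig_res.add_atom(_gemmi_atom(pose.ligand, i))
    lig_chain.add_residue(lig_res)
    model.add_chain(lig_chain)

    if len(pose.waters):
        w_chain = gemmi.Chain("W")
        for w in range(len(pose.waters)):
            res = gemmi.Residue()
            res.name = "WAT"
            res.seqid = gemmi.SeqId(w + 1, " ")
            res.het_flag = "H"
            o = gemmi.Atom()
            o.name = "O"
            o.element = gemmi.Element("O")
            o.pos = gemmi.Position(*pose.waters.oxygens[w])
            res.add_atom(o)
            for h in range(2):
                ha = gemmi.Atom()
                ha.name = f"H{h + 1}"
                ha.element = gemmi.Element("H")
                ha.pos = gemmi.Position(*pose.waters.hydrogens[w, h])
                res.add_atom(ha)
            w_chain.add_residue(res)
        model.add_chain(w_chain)

    st.add_model(model)
    text = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w") as fh:
                fh.write(text)
    return text


def _gemmi_atom(arr: AtomArray, i: int) -> gemmi.Atom:
    at = gemmi.Atom()
    at.name = arr.names[i]
    at.element = gemmi.Element(arr.elements[i].capitalize())
    at.pos = gemmi.Position(*arr.coords[i])
    at.occ = 1.0
    return at
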