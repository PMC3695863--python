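"""Minimal backbone-independent side-chain rotamer library.

Each residue type maps to its chi-angle definitions (the four atoms of the
dihedral plus the atom names that move when it turns) and a small discrete
rotamer set: the three canonical gauche+/gauche-/trans chi1 means with a
+/-10 degree deviation around each.  Residue types without an entry are left
fixed during repacking.
"""

from __future__ import annotations

from dataclasses import dataclass

CHI_DEVIATION = 10.0  # degrees around each canonical mean
_CANONICAL_CHI1 = (-60.0, 60.0, 180.0)


@dataclass(frozen=True)
class ChiDef:
    """One side-chain dihedral: its four atoms and the atoms it moves."""

    atoms: tuple[str, str, str, str]
    moving: tuple[str, ...]


# chi definitions per residue type; moving atoms listed explicitly because
# these minimal residues carry no side-chain bond graph
CHI_DEFS: dict[str, list[ChiDef]] = {
    "GLY": [],
    "ALA": [],
    "SER": [ChiDef(("N", "CA", "CB", "OG"), ("OG", "HG"))],
    "CYS": [ChiDef(("N", "CA", "CB", "SG"), ("SG",))],
    "THR": [ChiDef(("N", "CA", "CB", "OG1"), ("OG1", "CG2"))],
    "VAL": [ChiDef(("N", "CA", "CB", "CG1"), ("CG1", "CG2"))],
}


def rotamer_angles(resname: str) -> list[tuple[float, ...]] | None:
    """Discrete chi assignments for a residue type, or None if unknown.

    Types with no rotatable chi return a single empty assignment.
    """
    if resname not in CHI_DEFS:
        return None
    n_chi = len(CHI_DEFS[resname])
    if n_chi == 0:
        return [()]
    candidates = []
    for mean in _CANONICAL_CHI1:
        for dev in (-CHI_DEVIATION, 0.0, CHI_DEVIATION):
            candidates.append(mean + dev)
    # single-chi types only in this minimal library
    return [(c,) for c in candidates]
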