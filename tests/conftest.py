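"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from waterdock import (
    Atom,
    LigandModel,
    Pose,
    Structure,
    WaterSet,
    assign_atom_types,
    make_toy_pocket,
)
from waterdock.fixtures import ToyPocketSpec


@pytest.fixture(scope="session")
def toy():
    """Default toy pocket (tight bridging water): (structure, ligand, waters, pose)."""
    return make_toy_pocket()


@pytest.fixture(scope="session")
def toy_loose():
    return make_toy_pocket(ToyPocketSpec(bridge_water="loose"))


@pytest.fixture(scope="session")
def toy_dry():
    return make_toy_pocket(ToyPocketSpec(bridge_water=None))


def build_structure(spec):
    """Structure from [(name, element, xyz, resname, resnum, chain)], typed."""
    atoms, chains, rnames, rnums = [], [], [], []
    for name, el, xyz, rname, rnum, chain in spec:
        atoms.append(Atom(name, el, np.asarray(xyz, float), is_hydrogen=(el == "H")))
        chains.append(chain)
        rnames.append(rname)
        rnums.append(rnum)
    st = Structure(atoms, chains, rnames, rnums)
    assign_atom_types(st)
    return st


def build_ligand(spec, bonds):
    """LigandModel from [(name, element, xyz)], typed."""
    atoms = [
        Atom(name, el, np.asarray(xyz, float), is_hydrogen=(el == "H"))
        for name, el, xyz in spec
    ]
    lig = LigandModel(atoms, bonds)
    assign_atom_types(lig)
    return lig


def single_atom_protein(xyz=(0.0, 0.0, 0.0), element="C", name="CA"):
    return build_structure([(name, element, xyz, "GLY", 1, "A")])


def no_waters():
    return WaterSet()


def make_pose(structure, ligand, waters=None):
    return Pose(structure, ligand, waters if waters is not None else WaterSet())
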