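"""PDB I/O, normalization, typing, and ligand topology."""

from __future__ import annotations

import io

import numpy as np
import pytest

from waterdock import (
    WaterdockError,
    WaterSet,
    assign_atom_types,
    ligand_descriptors,
    read_complex,
    write_model,
)
from waterdock.structure import (
    Atom,
    ConnectivityError,
    LigandMissingError,
    LigandModel,
    UnknownElementError,
    parse_params_table,
)

from .conftest import build_ligand


def _pdb_line(record, serial, name, resname, chain, resnum, xyz, element,
              altloc=" ", occ=1.0):
    nm = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {nm}{altloc}{resname:<3} {chain}{resnum:>4}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def _simple_complex_pdb():
    """Two protein chains (file order Q then B), a het ligand, one water."""
    lines = [
        _pdb_line("ATOM", 1, "N", "GLY", "Q", 1, (0.0, 0.0, 0.0), "N"),
        _pdb_line("ATOM", 2, "CA", "GLY", "Q", 1, (1.5, 0.0, 0.0), "C"),
        _pdb_line("ATOM", 3, "C", "GLY", "Q", 1, (2.2, 1.3, 0.0), "C"),
        _pdb_line("ATOM", 4, "O", "GLY", "Q", 1, (3.4, 1.3, 0.0), "O"),
        "TER",
        _pdb_line("ATOM", 5, "N", "ALA", "B", 7, (0.0, 8.0, 0.0), "N"),
        _pdb_line("ATOM", 6, "CA", "ALA", "B", 7, (1.5, 8.0, 0.0), "C"),
        "TER",
        _pdb_line("HETATM", 7, "C1", "LIG", "L", 1, (5.0, 5.0, 5.0), "C"),
        _pdb_line("HETATM", 8, "O1", "LIG", "L", 1, (6.4, 5.0, 5.0), "O"),
        _pdb_line("HETATM", 9, "O", "HOH", "S", 1, (8.0, 8.0, 8.0), "O"),
        "END",
    ]
    return "\n".join(lines) + "\n"


class TestReadComplex:
    def test_chains_renamed_in_order_of_appearance(self):
        structure, ligand, waters = read_complex(_simple_complex_pdb())
        assert sorted(set(structure.chain_ids)) == ["A", "B"]
        # chain Q appeared first, so it becomes A
        assert structure.chain_ids[0] == "A"
        assert structure.res_names[:4] == ["GLY"] * 4

    def test_ligand_and_water_extracted(self):
        structure, ligand, waters = read_complex(_simple_complex_pdb())
        assert sorted(ligand.names) == ["C1", "O1"]
        assert len(waters) == 1
        np.testing.assert_allclose(waters.oxygens[0], [8.0, 8.0, 8.0])
        waters.copy()  # constructed hydrogens satisfy rigid geometry

    def test_largest_het_residue_wins(self):
        lines = [
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 2, "C1", "SML", "L", 1, (5.0, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 3, "C1", "BIG", "L", 2, (9.0, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 4, "C2", "BIG", "L", 2, (10.5, 0.0, 0.0), "C"),
            "END",
        ]
        _, ligand, _ = read_complex("\n".join(lines) + "\n")
        assert sorted(ligand.names) == ["C1", "C2"]

    def test_altloc_keeps_highest_occupancy(self):
        lines = [
            _pdb_line("ATOM", 1, "N", "GLY", "A", 1, (0.0, 0.0, 0.0), "N"),
            _pdb_line("ATOM", 2, "CA", "GLY", "A", 1, (1.0, 0.0, 0.0), "C",
                      altloc="A", occ=0.4),
            _pdb_line("ATOM", 3, "CA", "GLY", "A", 1, (2.0, 0.0, 0.0), "C",
                      altloc="B", occ=0.6),
            _pdb_line("HETATM", 4, "C1", "LIG", "L", 1, (8.0, 0.0, 0.0), "C"),
            "END",
        ]
        structure, _, _ = read_complex("\n".join(lines) + "\n")
        ca = structure.coords[structure.names.index("CA")]
        assert ca[0] == pytest.approx(2.0, abs=1e-3)
        assert structure.names.count("CA") == 1

    def test_terminal_caps_stripped(self):
        lines = [
            _pdb_line("ATOM", 1, "C", "ACE", "A", 0, (0.0, 0.0, 0.0), "C"),
            _pdb_line("ATOM", 2, "CA", "GLY", "A", 1, (1.5, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 3, "C1", "LIG", "L", 1, (8.0, 0.0, 0.0), "C"),
            "END",
        ]
        structure, _, _ = read_complex("\n".join(lines) + "\n")
        assert structure.res_names == ["GLY"]

    def test_noncanonical_residue_mapped(self):
        lines = [
            _pdb_line("ATOM", 1, "CA", "MSE", "A", 1, (0.0, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 2, "C1", "LIG", "L", 1, (8.0, 0.0, 0.0), "C"),
            "END",
        ]
        structure, _, _ = read_complex("\n".join(lines) + "\n")
        assert structure.res_names == ["MET"]

    def test_off_geometry_water_hydrogens_reidealized(self):
        lines = [
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 2, "C1", "LIG", "L", 1, (8.0, 0.0, 0.0), "C"),
            _pdb_line("HETATM", 3, "O", "HOH", "S", 1, (4.0, 4.0, 4.0), "O"),
            # wildly wrong O-H distances
            _pdb_line("HETATM", 4, "H1", "HOH", "S", 1, (6.0, 4.0, 4.0), "H"),
            _pdb_line("HETATM", 5, "H2", "HOH", "S", 1, (4.0, 6.0, 4.0), "H"),
            "END",
        ]
        _, _, waters = read_complex("\n".join(lines) + "\n")
        d = np.linalg.norm(waters.hydrogens[0] - waters.oxygens[0], axis=1)
        np.testing.assert_allclose(d, 0.9572, atol=1e-6)

    def test_missing_ligand_raises(self):
        lines = [
            _pdb_line("ATOM", 1, "CA", "GLY", "A", 1, (0.0, 0.0, 0.0), "C"),
            "END",
        ]
        with pytest.raises(LigandMissingError, match="no ligand found"):
            read_complex("\n".join(lines) + "\n")

    def test_connectivity_table_applied(self):
        table = "C1 C O1 none\nO1 O C1 donor\n"
        _, ligand, _ = read_complex(_simple_complex_pdb(), table)
        assert (0, 1, 1) in ligand.bonds
        assert ligand.roles[ligand.names.index("O1")] == "donor-heavy"

    def test_connectivity_table_unknown_atom_raises(self):
        table = "C1 C O9\nO9 O C1\n"
        with pytest.raises(ConnectivityError, match="absent from PDB ligand"):
            read_complex(_simple_complex_pdb(), table)


class TestParamsTable:
    def test_parses_orders_roles_and_comments(self):
        text = (
            "# ligand connectivity\n"
            "C1 C C2,O1:2\n"
            "C2 C C1 none\n"
            "O1 O C1:2 acceptor\n"
        )
        topo = parse_params_table(text)
        assert topo.names == ["C1", "C2", "O1"]
        assert (0, 2, 2) in topo.bonds
        assert (0, 1, 1) in topo.bonds
        assert topo.roles == {"C2": "none", "O1": "acceptor"}

    def test_dash_means_no_partner(self):
        topo = parse_params_table("C1 C -\n")
        assert topo.bonds == []

    def test_bad_line_raises(self):
        with pytest.raises(ConnectivityError, match="bad params line"):
            parse_params_table("C1 C\n")

    def test_unknown_partner_raises(self):
        with pytest.raises(ConnectivityError, match="unknown atom"):
            parse_params_table("C1 C O7\n")


class TestWriteModel:
    def test_round_trip_preserves_coordinates(self, toy):
        pose = toy[3]
        text = write_model(pose)
        structure, ligand, waters = read_complex(text)
        assert len(structure) == len(pose.structure)
        np.testing.assert_allclose(structure.coords, pose.structure.coords, atol=1e-3)
        order = [ligand.names.index(n) for n in pose.ligand.names]
        np.testing.assert_allclose(
            ligand.coords[order], pose.ligand.coords, atol=1e-3
        )
        np.testing.assert_allclose(waters.oxygens, pose.waters.oxygens, atol=1e-3)

    def test_normalized_chain_labels_in_output(self, toy):
        text = write_model(toy[3])
        assert any(" INH X" in line for line in text.splitlines())
        assert any(" WAT W" in line for line in text.splitlines())

    def test_writes_to_file_like(self, toy):
        buf = io.StringIO()
        text = write_model(toy[3], buf)
        assert buf.getvalue() == text

    def test_coordinate_overflow_raises(self, toy):
        pose = toy[3].copy()
        pose.ligand.coords = pose.ligand.coords + np.array([12000.0, 0.0, 0.0])
        with pytest.raises(WaterdockError, match="overflows fixed PDB columns"):
            write_model(pose)


class TestValidation:
    def test_waterset_rejects_bad_geometry(self):
        oxy = np.array([[0.0, 0.0, 0.0]])
        bad_h = np.array([[[2.0, 0.0, 0.0], [0.0, 2.0, 0.0]]])
        with pytest.raises(WaterdockError, match="O-H length"):
            WaterSet(oxy, bad_h)

    def test_disconnected_ligand_rejected(self):
        atoms = [
            Atom("C1", "C", [0.0, 0.0, 0.0]),
            Atom("C2", "C", [8.0, 0.0, 0.0]),
        ]
        with pytest.raises(ConnectivityError, match="not connected"):
            LigandModel(atoms, [])

    def test_unknown_element_rejected(self):
        lig = LigandModel([Atom("X1", "ZZ", [0.0, 0.0, 0.0])], [])
        with pytest.raises(UnknownElementError, match="unknown element"):
            assign_atom_types(lig)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(WaterdockError):
            Atom("C1", "C", [np.nan, 0.0, 0.0])


class TestLigandTopology:
    def test_toy_ligand_descriptors(self, toy):
        d = ligand_descriptors(toy[1])
        assert d.n_atoms == 10
        assert d.n_hbd == 2  # two hydroxyls
        assert d.n_hba == 3  # two hydroxyls + ketone oxygen
        assert d.n_rotatable == 3

    def test_butane_has_one_rotatable_bond(self):
        lig = build_ligand(
            [
                ("C1", "C", (0.0, 0.0, 0.0)),
                ("C2", "C", (1.5, 0.0, 0.0)),
                ("C3", "C", (2.3, 1.3, 0.0)),
                ("C4", "C", (3.8, 1.3, 0.0)),
            ],
            [(0, 1, 1), (1, 2, 1), (2, 3, 1)],
        )
        assert len(lig.rotatable_torsions) == 1

    def test_ethane_has_none(self):
        lig = build_ligand(
            [("C1", "C", (0.0, 0.0, 0.0)), ("C2", "C", (1.5, 0.0, 0.0))],
            [(0, 1, 1)],
        )
        assert lig.rotatable_torsions == []

    def test_ring_bonds_not_rotatable(self):
        pts = [
            (np.cos(t), np.sin(t), 0.0)
            for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ]
        lig = build_ligand(
            [(f"C{i+1}", "C", pts[i]) for i in range(6)],
            [(i, (i + 1) % 6, 1) for i in range(6)],
        )
        assert lig.rotatable_torsions == []

    def test_double_bonds_not_rotatable(self):
        lig = build_ligand(
            [
                ("C1", "C", (0.0, 0.0, 0.0)),
                ("C2", "C", (1.3, 0.0, 0.0)),
                ("C3", "C", (2.1, 1.2, 0.0)),
                ("C4", "C", (3.6, 1.2, 0.0)),
            ],
            [(0, 1, 1), (1, 2, 2), (2, 3, 1)],
        )
        assert lig.rotatable_torsions == []
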