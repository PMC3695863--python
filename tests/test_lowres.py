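"""Low-resolution movers: envelopes, composition, and the slide arithmetic."""

from __future__ import annotations

import numpy as np
import pytest

from waterdock import LowResParams, WaterdockError, run_low_res
from waterdock.lowres import (
    move_water_protein_centric,
    move_waters_ligand_centric,
    reorient_waters,
    rotate_ligand,
    shift_waters_independently,
    slide_together,
    translate_ligand,
)

from .conftest import build_ligand, make_pose, single_atom_protein

N_SEEDS = 20


def _intra_distances(lig):
    d = lig.coords[:, None, :] - lig.coords[None, :, :]
    return np.sqrt((d**2).sum(-1))


class TestTranslate:
    @pytest.mark.parametrize("seed", range(N_SEEDS))
    def test_centroid_shift_within_radius(self, toy, seed):
        pose = toy[3]
        out = translate_ligand(pose, rng=np.random.default_rng(seed))
        shift = np.linalg.norm(out.ligand.centroid - pose.ligand.centroid)
        assert shift <= 5.0 + 1e-9

    def test_zero_radius_is_identity(self, toy):
        pose = toy[3]
        out = translate_ligand(
            pose,
            LowResParams(translate_radius=0.0),
            rng=np.random.default_rng(0),
        )
        np.testing.assert_array_equal(out.ligand.coords, pose.ligand.coords)

    def test_rigid_move_preserves_internal_geometry(self, toy):
        pose = toy[3]
        out = translate_ligand(pose, rng=np.random.default_rng(2))
        np.testing.assert_allclose(
            _intra_distances(out.ligand), _intra_distances(pose.ligand), atol=1e-9
        )

    def test_carry_waters_moves_them_rigidly(self, toy):
        pose = toy[3]
        out = translate_ligand(
            pose, rng=np.random.default_rng(3), carry_waters=True
        )
        delta = out.ligand.centroid - pose.ligand.centroid
        np.testing.assert_allclose(
            out.waters.oxygens, pose.waters.oxygens + delta, atol=1e-9
        )
        np.testing.assert_allclose(
            out.waters.hydrogens, pose.waters.hydrogens + delta, atol=1e-9
        )

    def test_input_pose_unchanged(self, toy):
        pose = toy[3]
        before = pose.ligand.coords.copy()
        translate_ligand(pose, rng=np.random.default_rng(4))
        np.testing.assert_array_equal(pose.ligand.coords, before)


class TestRotate:
    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_about_centroid(self, toy, seed):
        pose = toy[3]
        out = rotate_ligand(pose, rng=np.random.default_rng(seed))
        np.testing.assert_allclose(
            out.ligand.centroid, pose.ligand.centroid, atol=1e-9
        )
        np.testing.assert_allclose(
            _intra_distances(out.ligand), _intra_distances(pose.ligand), atol=1e-9
        )

    def test_zero_tries_is_identity(self, toy):
        pose = toy[3]
        out = rotate_ligand(
            pose,
            LowResParams(rotate_tries_ligand=0),
            rng=np.random.default_rng(0),
        )
        np.testing.assert_array_equal(out.ligand.coords, pose.ligand.coords)


class TestSlideTogether:
    def test_arithmetic_contact_case(self):
        # C at origin, ligand C at 10.05: contact at 3.4 A, 0.1 A steps from
        # 10.05 cross contact between steps 66 and 67; backing off one step
        # leaves the gap in (3.4, 3.5]
        protein = single_atom_protein((0.0, 0.0, 0.0))
        ligand = build_ligand([("C1", "C", (10.05, 0.0, 0.0))], [])
        out = slide_together(make_pose(protein, ligand))
        gap = float(out.ligand.coords[0, 0])
        assert 3.4 < gap <= 3.5 + 1e-9
        assert gap == pytest.approx(10.05 - 66 * 0.1, abs=1e-9)

    def test_already_in_contact_unchanged(self):
        protein = single_atom_protein((0.0, 0.0, 0.0))
        ligand = build_ligand([("C1", "C", (3.0, 0.0, 0.0))], [])
        pose = make_pose(protein, ligand)
        out = slide_together(pose)
        np.testing.assert_array_equal(out.ligand.coords, pose.ligand.coords)

    def test_no_protein_raises(self, toy):
        from waterdock.structure import Structure

        pose = toy[3].copy()
        pose.structure = Structure([], [], [], [])
        with pytest.raises(WaterdockError, match="no protein atoms"):
            slide_together(pose)

    def test_coincident_centroids_raise(self):
        protein = single_atom_protein((0.0, 0.0, 0.0))
        # ligand centroid on the protein centroid but atoms out of contact
        ligand = build_ligand(
            [("C1", "C", (8.0, 0.0, 0.0)), ("C2", "C", (-8.0, 0.0, 0.0))],
            [(0, 1, 1)],
        )
        with pytest.raises(WaterdockError, match="slide direction degenerate"):
            slide_together(make_pose(protein, ligand))


class TestWaterMoves:
    @pytest.mark.parametrize("seed", range(N_SEEDS))
    def test_protein_centric_shift_within_four_angstrom(self, toy, seed):
        pose = toy[3]
        out = move_water_protein_centric(pose, rng=np.random.default_rng(seed))
        shift = np.linalg.norm(out.waters.oxygens - pose.waters.oxygens, axis=1)
        assert np.all(shift <= 4.0 + 1e-9)

    @pytest.mark.parametrize("seed", range(N_SEEDS))
    def test_ligand_centric_independent_shift_within_one_angstrom(self, toy, seed):
        pose = toy[3]
        out = shift_waters_independently(pose, rng=np.random.default_rng(seed))
        shift = np.linalg.norm(out.waters.oxygens - pose.waters.oxygens, axis=1)
        assert np.all(shift <= 1.0 + 1e-9)

    def test_reorient_keeps_oxygen_and_geometry(self, toy):
        pose = toy[3]
        out = reorient_waters(pose, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(out.waters.oxygens, pose.waters.oxygens)
        # WaterSet construction re-validates rigid geometry
        out.waters.copy()

    def test_reorient_never_worsens_orientation_energy(self, toy):
        from waterdock.lowres import _water_orientation_energy
        from waterdock import ScoreFunction

        pose = toy[3]
        sf = ScoreFunction()
        before = _water_orientation_energy(pose, 0, sf)
        out = reorient_waters(pose, rng=np.random.default_rng(6), sf=sf)
        assert _water_orientation_energy(out, 0, sf) <= before + 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_ligand_centric_composition(self, toy, seed):
        pose = toy[3]
        from waterdock import ScoreFunction

        combined = move_waters_ligand_centric(
            pose, rng=np.random.default_rng(seed)
        )
        rng = np.random.default_rng(seed)
        sf = ScoreFunction()
        manual = translate_ligand(
            pose, rng=rng, sf=sf, carry_waters=True
        )
        manual = shift_waters_independently(manual, rng=rng, sf=sf)
        manual = rotate_ligand(manual, rng=rng, sf=sf, carry_waters=True)
        manual = reorient_waters(manual, rng=rng, sf=sf)
        np.testing.assert_array_equal(combined.ligand.coords, manual.ligand.coords)
        np.testing.assert_array_equal(combined.waters.oxygens, manual.waters.oxygens)
        np.testing.assert_array_equal(
            combined.waters.hydrogens, manual.waters.hydrogens
        )


class TestRunLowRes:
    @pytest.mark.parametrize(
        "protocol", ["standard", "protein_centric", "ligand_centric"]
    )
    def test_protocols_run_and_flag_strain(self, toy, protocol):
        out = run_low_res(toy[3], protocol, rng=np.random.default_rng(1))
        assert isinstance(out.strained, bool)
        assert len(out.waters) == 1
        np.testing.assert_allclose(
            _intra_distances(out.ligand), _intra_distances(toy[3].ligand), atol=1e-9
        )

    def test_deterministic_under_seed(self, toy):
        a = run_low_res(toy[3], "ligand_centric", rng=np.random.default_rng(9))
        b = run_low_res(toy[3], "ligand_centric", rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a.ligand.coords, b.ligand.coords)
        np.testing.assert_array_equal(a.waters.oxygens, b.waters.oxygens)

    def test_unknown_protocol_raises(self, toy):
        with pytest.raises(WaterdockError, match="unknown protocol"):
            run_low_res(toy[3], "hybrid", rng=np.random.default_rng(0))
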