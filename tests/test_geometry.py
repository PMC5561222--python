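import numpy as np
import pytest

from trxss import geometry, synthetic_data
from trxss.models import StructureModel


def _structure(coords, resnum=None, chain=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        chain=np.full(n, "A") if chain is None else np.asarray(chain),
        resnum=np.arange(1, n + 1) if resnum is None else np.asarray(resnum),
        resname=np.full(n, "ALA"),
        coords=coords,
    )


def _rot_z(deg):
    t = np.radians(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
    )


class TestSuperpose:
    def test_identity(self, toy_dimer):
        transform, rmsd = geometry.superpose(toy_dimer, toy_dimer)
        assert rmsd < 1e-12
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_inverts_constructed_transform(self, toy_dimer):
        moved = toy_dimer.with_coords(
            toy_dimer.coords @ _rot_z(30.0).T + np.array([4.0, -2.0, 7.0])
        )
        transform, rmsd = geometry.superpose(moved, toy_dimer)
        assert rmsd < 1e-9
        assert np.abs(transform.apply(moved.coords) - toy_dimer.coords).max() < 1e-9

    def test_mirror_image_gets_proper_rotation(self, rng):
        coords = rng.normal(size=(30, 3))
        ref = _structure(coords)
        mirrored = _structure(coords * np.array([1.0, 1.0, -1.0]))
        transform, rmsd = geometry.superpose(mirrored, ref)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_too_few_or_collinear_sites_rejected(self):
        line = _structure(np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)]))
        with pytest.raises(ValueError):
            geometry.superpose(line, line)
        two = _structure([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            geometry.superpose(two, two)


class TestMeanDisplacement:
    def test_identical_pairs_give_zero_field(self, toy_dimer):
        field = geometry.mean_displacement([(toy_dimer, toy_dimer)] * 2)
        assert np.abs(field.magnitude).max() < 1e-12

    def test_rotation_chord_formula(self, toy_dimer):
        """A 10 deg z rotation displaces each site by 2 r sin(5 deg)."""
        sel = [("A", 224, 385), ("B", 224, 385)]
        mask = toy_dimer.range_mask(sel)
        coords = toy_dimer.coords.copy()
        coords[mask] = coords[mask] @ _rot_z(10.0).T
        light = toy_dimer.with_coords(coords)
        field = geometry.mean_displacement([(toy_dimer, light)])
        radius = np.linalg.norm(toy_dimer.coords[mask][:, :2], axis=1)
        expected = 2 * radius * np.sin(np.radians(5.0))
        assert np.abs(field.magnitude[mask] - expected).max() < 1e-9
        lov_mask = toy_dimer.range_mask([("A", 11, 127), ("B", 11, 127)])
        assert np.abs(field.magnitude[lov_mask]).max() < 1e-9

    def test_opposite_rotations_cancel_in_mean_vector(self, toy_dimer):
        sel = [("A", 224, 385), ("B", 224, 385)]
        mask = toy_dimer.range_mask(sel)
        pairs = []
        for sign in (+1.0, -1.0):
            coords = toy_dimer.coords.copy()
            coords[mask] = coords[mask] @ _rot_z(sign * 8.0).T
            pairs.append((toy_dimer, toy_dimer.with_coords(coords)))
        field = geometry.mean_displacement(pairs)
        # chords of +/- theta rotations cancel to first order; the exact
        # residual mean vector has length (1 - cos theta) * radius
        radius = np.linalg.norm(toy_dimer.coords[mask][:, :2], axis=1)
        bound = (1 - np.cos(np.radians(8.0))) * radius
        assert np.all(field.magnitude[mask] <= bound + 1e-9)
        assert field.mean_magnitude[mask].max() > 0.1  # individual motions real


class TestChiAngle:
    def _three_blob_structure(self, p1, p2, p3):
        """27 sites in three clusters whose centroids are exactly p1, p2, p3."""
        offsets = np.array(
            [[dx, dy, dz] for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (0,)],
            dtype=float,
        )
        ranges = geometry.ResidueRanges(
            {
                "lov": [("A", 11, 19)],
                "hinge": [("A", 146, 154)],
                "dhp": [("A", 170, 178)],
            }
        )
        coords = np.vstack([p + offsets for p in (p1, p2, p3)])
        resnum = np.concatenate(
            [np.arange(11, 20), np.arange(146, 155), np.arange(170, 179)]
        )
        return _structure(coords, resnum=resnum), ranges

    def test_collinear_centres_give_180(self):
        s, r = self._three_blob_structure(
            np.array([0.0, 0, -20]), np.array([0.0, 0, 0]), np.array([0.0, 0, 25])
        )
        assert geometry.chi_angle(s, r) == pytest.approx(180.0)

    def test_right_angle(self):
        s, r = self._three_blob_structure(
            np.array([10.0, 0, 0]), np.array([0.0, 0, 0]), np.array([0.0, 10.0, 0])
        )
        assert geometry.chi_angle(s, r) == pytest.approx(90.0)

    def test_constructed_hinge_change(self):
        """Bending the outer arm by 15 deg changes chi by exactly 15 deg."""
        s, r = self._three_blob_structure(
            np.array([0.0, 0, -20]), np.array([0.0, 0, 0]), np.array([0.0, 0, 25])
        )
        chi0 = geometry.chi_angle(s, r)
        coords = s.coords.copy()
        arm = s.resnum >= 170  # rotate the outer arm about x through the hinge
        t = np.radians(15.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]]
        )
        coords[arm] = coords[arm] @ rot.T
        bent = s.with_coords(coords)
        assert chi0 - geometry.chi_angle(bent, r) == pytest.approx(15.0, abs=0.1)


class TestPsiDihedral:
    def _four_blob_structure(self, p1, p2, p3, p4):
        offsets = np.array([[0.5, 0, 0], [-0.5, 0, 0], [0, 0.5, 0], [0, -0.5, 0]])
        coords = np.vstack([p + offsets for p in (p1, p2, p3, p4)])
        chain = np.array(["A"] * 4 + ["B"] * 4 + ["A"] * 4 + ["B"] * 4)
        resnum = np.concatenate(
            [np.arange(11, 15), np.arange(11, 15), np.arange(224, 228), np.arange(224, 228)]
        )
        return StructureModel(
            chain=chain, resnum=resnum, resname=np.full(16, "ALA"), coords=coords
        )

    def test_cis_is_zero(self):
        s = self._four_blob_structure(
            np.array([1.0, 5.0, 0.0]),
            np.array([0.0, 0.0, 0.0]),
            np.array([0.0, 0.0, 10.0]),
            np.array([1.0, 5.0, 10.0]),
        )
        assert geometry.psi_dihedral(s) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        s = self._four_blob_structure(
            np.array([1.0, 5.0, 0.0]),
            np.array([0.0, 0.0, 0.0]),
            np.array([0.0, 0.0, 10.0]),
            np.array([-1.0, -5.0, 10.0]),
        )
        assert abs(geometry.psi_dihedral(s)) == pytest.approx(180.0, abs=1e-9)

    def test_recovers_imposed_rotation(self, toy_dimer):
        psi0 = geometry.psi_dihedral(toy_dimer)
        perturbed = synthetic_data.perturb_conformer(toy_dimer, d_psi=11.0)
        assert geometry.psi_dihedral(perturbed) - psi0 == pytest.approx(
            11.0, abs=1e-6
        )

    def test_rigid_motion_invariance(self, toy_dimer):
        moved = toy_dimer.with_coords(
            toy_dimer.coords @ _rot_z(47.0).T + np.array([3.0, 1.0, -9.0])
        )
        assert geometry.psi_dihedral(moved) == pytest.approx(
            geometry.psi_dihedral(toy_dimer), abs=1e-9
        )
        assert geometry.chi_angle(moved) == pytest.approx(
            geometry.chi_angle(toy_dimer), abs=1e-9
        )


class TestDistanceMatrices:
    def test_two_sites(self):
        s = _structure([[0, 0, 0], [0, 0, 5.0]])
        assert np.allclose(
            geometry.distance_matrix(s), [[0.0, 5.0], [5.0, 0.0]]
        )

    def test_matches_brute_force(self, rng):
        coords = rng.normal(scale=10, size=(30, 3))
        s = _structure(coords)
        mat = geometry.distance_matrix(s)
        brute = np.array(
            [[np.linalg.norm(a - b) for b in coords] for a in coords]
        )
        assert np.abs(mat - brute).max() < 1e-12

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(15, 3))
        s = _structure(coords)
        moved = _structure(coords @ _rot_z(33.0).T + 4.0)
        assert np.abs(
            geometry.distance_matrix(s) - geometry.distance_matrix(moved)
        ).max() < 1e-9

    def test_double_difference_zero_for_equal_states(self, toy_dimer):
        sel = [("A", 224, 377), ("B", 224, 377)]
        out = geometry.double_difference(toy_dimer, toy_dimer, toy_dimer, sel)
        assert np.abs(out).max() == 0.0

    def test_double_difference_independent_of_dark(self, toy_dimer):
        sel = [("A", 224, 377), ("B", 224, 377)]
        a = synthetic_data.perturb_conformer(toy_dimer, d_psi=5.0)
        b = synthetic_data.perturb_conformer(
            toy_dimer, d_chi=6.0, mobile=[("A", 224, 385)]
        )
        dark2 = synthetic_data.perturb_conformer(
            toy_dimer, jitter_sigma=1.0, seed=3
        )
        out1 = geometry.double_difference(toy_dimer, a, b, sel)
        out2 = geometry.double_difference(dark2, a, b, sel)
        assert np.array_equal(out1, out2)

    def test_translation_toward_other_block_is_negative(self):
        """A block moving toward another produces negative cross entries."""
        n = 6
        block1 = np.column_stack([np.zeros(n), np.zeros(n), np.arange(n, dtype=float)])
        block2 = block1 + np.array([20.0, 0, 0])
        dark = _structure(np.vstack([block1, block2]))
        state_a = dark.copy()
        closer = np.vstack([block1, block2 - np.array([5.0, 0, 0])])
        state_b = dark.with_coords(closer)
        out = geometry.double_difference(dark, state_a, state_b)
        cross = out[:n, n:]
        assert np.all(cross < 0)
        assert np.abs(out[:n, :n]).max() < 1e-12
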