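"""Geometric kernels: signed torsions, centroids, distances, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ligswitch as ls
from ligswitch.errors import ConfigError, GeometryError

from conftest import make_frames, torsion_oracle, wrapped_diff


class TestTorsion:
    @pytest.mark.parametrize(
        "p4,expected",
        [
            ((1, 1, 0), 0.0),     # syn-periplanar (eclipsed)
            ((1, -1, 0), 180.0),  # anti-periplanar (trans)
            ((1, 0, 1), 90.0),    # perpendicular, positive handedness
            ((1, 0, -1), -90.0),  # perpendicular, negative handedness
        ],
    )
    def test_canonical_configurations(self, p4, expected):
        # sign convention cross-checked against MDAnalysis, mdtraj, biotite
        angle = ls.torsion((0, 1, 0), (0, 0, 0), (1, 0, 0), p4)
        assert angle == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_projection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            pts = rng.normal(size=(4, 3)) * 3.0
            assert wrapped_diff(ls.torsion(*pts), torsion_oracle(*pts)) < 1e-9

    def test_invariant_under_rigid_transforms(self):
        rng = np.random.default_rng(5)
        pts = ls.build_torsion_quartet(-73.2)
        ref = ls.torsion(*pts)
        for rot in Rotation.random(50, rng=rng):
            moved = pts @ rot.as_matrix().T + rng.normal(size=3) * 10.0
            assert wrapped_diff(ls.torsion(*moved), ref) < 1e-9

    def test_sign_flips_under_mirror_reflection(self):
        pts = ls.build_torsion_quartet(37.0)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert ls.torsion(*mirrored) == pytest.approx(-37.0, abs=1e-9)

    def test_periodicity_of_construction(self):
        for t in (-150.0, 10.0, 120.0):
            a = ls.torsion(*ls.build_torsion_quartet(t))
            b = ls.torsion(*ls.build_torsion_quartet(t + 360.0))
            assert wrapped_diff(a, t) < 1e-9
            assert wrapped_diff(b, t) < 1e-9

    def test_output_range_half_open(self):
        # the wrap prefers +180 over -180 and never leaves (-180, 180]
        assert ls.wrap_degrees(-180.0) == 180.0
        assert ls.wrap_degrees(540.0) == 180.0
        value = ls.torsion(*ls.build_torsion_quartet(-180.0))
        assert -180.0 < value <= 180.0
        assert wrapped_diff(value, 180.0) < 1e-9

    def test_coincident_central_atoms(self):
        with pytest.raises(GeometryError):
            ls.torsion((0, 1, 0), (0, 0, 0), (0, 0, 0), (1, 1, 0))

    def test_collinear_triple(self):
        with pytest.raises(GeometryError):
            ls.torsion((2, 0, 0), (1, 0, 0), (0, 0, 0), (0, 1, 0))


class TestTorsionSeries:
    def test_round_trips_prescribed_torsions(self):
        targets = [-90.0, 90.0, 180.0]
        coords = np.stack([ls.build_torsion_quartet(t) for t in targets])
        series = ls.torsion_series(make_frames(coords), [0, 1, 2, 3])
        np.testing.assert_allclose(series.values, targets, atol=1e-6)

    def test_single_frame(self):
        coords = ls.build_torsion_quartet(42.0)[None]
        series = ls.torsion_series(make_frames(coords), [0, 1, 2, 3])
        assert len(series) == 1

    def test_degenerate_frame_named_in_error(self):
        coords = np.stack(
            [ls.build_torsion_quartet(10.0), ls.build_torsion_quartet(10.0)]
        )
        coords[1, 2] = coords[1, 1]  # p2 == p3 in frame 1
        with pytest.raises(GeometryError, match="frame 1"):
            ls.torsion_series(make_frames(coords), [0, 1, 2, 3])


class TestRingCentroid:
    def test_hexagon_centroid_is_center(self):
        ang = np.radians(np.arange(6) * 60.0)
        hexagon = 1.39 * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        cen = ls.ring_centroid(make_frames(hexagon[None]), range(6))
        np.testing.assert_allclose(cen, [[0, 0, 0]], atol=1e-9)

    def test_translated_frame(self):
        ang = np.radians(np.arange(6) * 60.0)
        hexagon = 1.39 * np.column_stack([np.cos(ang), np.sin(ang), np.zeros(6)])
        coords = np.stack([hexagon, hexagon + np.array([1.0, 2.0, 3.0])])
        cen = ls.ring_centroid(make_frames(coords), range(6))
        np.testing.assert_allclose(cen[1], [1, 2, 3], atol=1e-9)

    def test_three_atom_ring_is_plain_mean(self):
        tri = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0]], dtype=float)
        cen = ls.ring_centroid(make_frames(tri[None]), [0, 1, 2])
        np.testing.assert_allclose(cen, tri.mean(axis=0)[None])

    def test_too_few_atoms(self):
        with pytest.raises(ConfigError):
            ls.ring_centroid(make_frames(np.zeros((1, 4, 3))), [0, 1])


class TestMinDistance:
    def test_minimum_of_pair(self):
        coords = np.array([[[0, 0, 0], [0, 0, 4], [0, 0, 5]]], dtype=float)
        d = ls.min_distance_series(make_frames(coords), [0, 1], np.array([2]))
        assert d.values[0] == pytest.approx(1.0)

    def test_self_distance_zero(self):
        coords = np.zeros((1, 1, 3))
        d = ls.min_distance_series(make_frames(coords), [0], np.array([0]))
        assert d.values[0] == 0.0

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(4, 8, 3)) * 5.0
        frames = make_frames(coords)
        group_a, group_b = [0, 2, 4, 5, 7], [1, 3, 6]
        d = ls.min_distance_series(frames, group_a, np.array(group_b))
        for f in range(4):
            brute = min(
                np.linalg.norm(coords[f, a] - coords[f, b])
                for a in group_a
                for b in group_b
            )
            assert d.values[f] == pytest.approx(brute, abs=1e-12)

    def test_per_frame_point_target(self):
        coords = np.zeros((2, 1, 3))
        points = np.array([[0, 0, 3.0], [0, 4.0, 0]])
        d = ls.min_distance_series(make_frames(coords), [0], points)
        np.testing.assert_allclose(d.values, [3.0, 4.0])

    def test_empty_group(self):
        with pytest.raises(ConfigError):
            ls.min_distance_series(make_frames(np.zeros((1, 2, 3))), [], np.array([0]))


class TestKabsch:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        rot, trans, rmsd = ls.kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        true_rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        moved = pts @ true_rot.T + np.array([1.0, 0.0, 0.0])
        rot, trans, rmsd = ls.kabsch_superpose(pts, moved)
        np.testing.assert_allclose(rot, true_rot, atol=1e-9)
        np.testing.assert_allclose(trans, [1.0, 0.0, 0.0], atol=1e-9)
        assert rmsd < 1e-9

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.normal(size=(2, 6, 3))
            rot, _, _ = ls.kabsch_superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_is_symmetric(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(2, 15, 3))
        _, _, r_ab = ls.kabsch_superpose(a, b)
        _, _, r_ba = ls.kabsch_superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ConfigError):
            ls.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestLigandRmsd:
    def _system(self, n_frames=3):
        rng = np.random.default_rng(9)
        receptor = rng.normal(size=(6, 3)) * 4.0
        ligand = rng.normal(size=(4, 3)) + np.array([8.0, 0, 0])
        base = np.vstack([receptor, ligand])
        return np.repeat(base[None], n_frames, axis=0)

    def test_rigid_motion_of_everything_gives_zero(self):
        coords = self._system()
        rng = np.random.default_rng(10)
        for f, rot in enumerate(Rotation.random(3, rng=rng)):
            coords[f] = coords[f] @ rot.as_matrix().T + rng.normal(size=3) * 5.0
        series = ls.ligand_rmsd_series(make_frames(coords), range(6), range(6, 10))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_pure_ligand_translation_measured_exactly(self):
        coords = self._system(2)
        coords[1, 6:10] += np.array([0.0, 2.0, 0.0])
        series = ls.ligand_rmsd_series(make_frames(coords), range(6), range(6, 10))
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert series.values[1] == pytest.approx(2.0, abs=1e-9)

    def test_reference_frame_rmsd_is_zero(self):
        coords = self._system(4)
        coords += np.random.default_rng(12).normal(scale=0.3, size=coords.shape)
        series = ls.ligand_rmsd_series(
            make_frames(coords), range(6), range(6, 10), reference_frame=2
        )
        assert series.values[2] == pytest.approx(0.0, abs=1e-9)

    def test_two_pose_trajectory_is_bimodal(self):
        """RMSD separates generator poses, matching true labels >=95%."""
        params = ls.SyntheticParams(seed=21, n_frames=500, n_replicas=1)
        rep = ls.simulate_series(params)[0]
        frames = ls.series_to_coordinates(rep, params)
        spec = ls.synthetic_selection_spec(params)
        fit = ls.resolve_selection(frames, spec, "receptor_fit_atoms")
        lig = ls.resolve_selection(frames, spec, "ligand_quartet")
        # reference must be the docked starting pose (MINUS_AC by construction)
        series = ls.ligand_rmsd_series(frames, fit, lig, reference_frame=0)
        split = series.values > np.mean(
            [series.values.min(), series.values.max()]
        )
        predicted = np.where(split, "PLUS_AC", "MINUS_AC")
        agreement = np.mean(predicted == rep.chain_states.labels)
        assert agreement >= 0.95
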