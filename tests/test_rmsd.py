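"""Pairwise RMSD, Kabsch superposition, matrix, and reference curves."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

from lagrmsd import (
    RMSDMatrix,
    Trajectory,
    kabsch,
    reference_curves,
    rmsd_matrix,
    rmsd_pair,
)
from .conftest import brute_force_aligned_rmsd, rotation_grid

TRIANGLE = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)

frames = arrays(
    float,
    st.tuples(st.integers(3, 8), st.just(3)),
    elements=st.floats(-100, 100, allow_nan=False),
)


class TestRmsdPair:
    @pytest.mark.parametrize("align", [False, True])
    def test_identical_frames_zero(self, align, rng):
        f = rng.standard_normal((6, 3))
        assert rmsd_pair(f, f, align=align) == pytest.approx(0.0, abs=1e-12)

    def test_single_atom_unit_displacement(self):
        a = np.zeros((1, 3))
        b = np.array([[1.0, 0.0, 0.0]])
        assert rmsd_pair(a, b, align=False) == 1.0

    def test_rigid_motion_invariance(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        b = TRIANGLE @ R.T + np.array([1.0, 2.0, 3.0])
        assert rmsd_pair(TRIANGLE, b, align=True) == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated_unaligned_value(self):
        b = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 1]], dtype=float)
        # only the third atom moves, by 1: sqrt(1/3)
        assert rmsd_pair(TRIANGLE, b, align=False) == pytest.approx(np.sqrt(1 / 3))

    def test_mismatched_atom_counts(self):
        with pytest.raises(ValueError, match="atom counts"):
            rmsd_pair(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_nonpositive_weight_errors(self):
        with pytest.raises(ValueError, match="positive"):
            rmsd_pair(TRIANGLE, TRIANGLE, weights=[1.0, 0.0, 1.0])

    def test_weighted_rmsd_uses_normalized_weights(self):
        a = np.zeros((2, 3))
        b = np.array([[1.0, 0, 0], [0, 0, 0]])
        # weight 3:1 on the moved atom -> sqrt(3/4)
        got = rmsd_pair(a, b, align=False, weights=[3.0, 1.0])
        assert got == pytest.approx(np.sqrt(0.75))

    @given(a=frames.filter(lambda x: x.shape[0] >= 3))
    def test_symmetry_and_self_distance(self, a):
        b = a[::-1].copy()
        b = np.ascontiguousarray(b)
        assert rmsd_pair(a, a, align=False) == 0.0
        assert rmsd_pair(a, b, align=False) == pytest.approx(
            rmsd_pair(b, a, align=False), rel=1e-12
        )

    @given(seed=st.integers(0, 10_000))
    def test_alignment_never_increases_rmsd(self, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal((6, 3))
        b = r.standard_normal((6, 3))
        assert rmsd_pair(a, b, align=True) <= rmsd_pair(a, b, align=False) + 1e-12

    @given(seed=st.integers(0, 10_000))
    def test_aligned_rmsd_rigid_invariant(self, seed):
        r = np.random.default_rng(seed)
        a = r.standard_normal((6, 3))
        b = r.standard_normal((6, 3))
        R = Rotation.random(rng=int(seed)).as_matrix()
        b_moved = b @ R.T + r.standard_normal(3)
        assert rmsd_pair(a, b_moved, align=True) == pytest.approx(
            rmsd_pair(a, b, align=True), abs=1e-9
        )


class TestKabsch:
    def test_identity_on_equal_frames(self):
        res = kabsch(TRIANGLE, TRIANGLE)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-12)
        assert res.rmsd_after == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        res = kabsch(TRIANGLE, TRIANGLE + 5.0)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(res.translation, [-5, -5, -5], atol=1e-9)
        assert res.rmsd_after == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_proper(self, rng):
        res = kabsch(rng.standard_normal((6, 3)), rng.standard_normal((6, 3)))
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        grid = rotation_grid(step_deg=4.0, n_axes=8000)
        for _ in range(5):
            a = rng.standard_normal((6, 3))
            b = rng.standard_normal((6, 3))
            bf = brute_force_aligned_rmsd(a, b, grid)
            kb = kabsch(a, b).rmsd_after
            assert kb <= bf + 1e-9
            assert bf - kb < 5e-3

    def test_degenerate_single_atom_no_crash(self):
        res = kabsch(np.zeros((1, 3)), np.ones((1, 3)))
        assert res.rmsd_after == pytest.approx(0.0, abs=1e-12)


class TestRmsdMatrix:
    def test_two_frame_single_atom(self):
        traj = Trajectory(
            coords=np.array([[[0, 0, 0]], [[1, 0, 0]]], float), times=[0.0, 1.0]
        )
        m = rmsd_matrix(traj, align=False)
        np.testing.assert_allclose(m.values, [[0, 1], [1, 0]])

    @pytest.mark.parametrize("align", [False, True])
    def test_matches_elementwise_pairs(self, align, rng):
        coords = rng.standard_normal((5, 4, 3))
        traj = Trajectory(coords=coords, times=np.arange(5.0))
        m = rmsd_matrix(traj, align=align)
        assert np.array_equal(m.values, m.values.T)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(
                    rmsd_pair(coords[i], coords[j], align=align), rel=1e-12
                )

    def test_single_frame_rejected(self):
        traj = Trajectory(coords=np.zeros((1, 2, 3)), times=[0.0])
        with pytest.raises(ValueError, match="2 frames"):
            rmsd_matrix(traj)


class TestReferenceCurves:
    def test_hand_computed_three_frames(self):
        m = RMSDMatrix(
            values=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float),
            times=[0.0, 1.0, 2.0],
        )
        ref = reference_curves(m)
        np.testing.assert_allclose(ref.per_frame_mean, [1.5, 1.0, 1.5])
        assert ref.idx_min == 1
        assert ref.idx_max == 0  # tie between 0 and 2 broken to the smaller index
        np.testing.assert_array_equal(ref.curve_first, [0, 1, 2])
        np.testing.assert_array_equal(ref.curve_min, [1, 0, 1])

    def test_two_frame_symmetric(self):
        m = RMSDMatrix(values=np.array([[0, 3.0], [3.0, 0]]), times=[0.0, 1.0])
        ref = reference_curves(m)
        np.testing.assert_allclose(ref.per_frame_mean, [3.0, 3.0])
        assert ref.idx_max == 0 and ref.idx_min == 0

    def test_each_curve_zero_at_its_reference(self, rng):
        coords = rng.standard_normal((6, 5, 3))
        m = rmsd_matrix(Trajectory(coords=coords, times=np.arange(6.0)), align=False)
        ref = reference_curves(m)
        assert ref.curve_first[0] == 0.0
        assert ref.curve_max[ref.idx_max] == 0.0
        assert ref.curve_min[ref.idx_min] == 0.0
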