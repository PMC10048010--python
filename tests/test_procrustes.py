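"""Centroid size, pairwise superimposition and GPA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crownmorph as cm
from crownmorph.errors import (
    DegenerateConfigurationError,
    InvalidInputError,
    ShapeMismatchError,
)
from oracles import pairwise_distance_by_optimizer

SQUARE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestCentroidSize:
    def test_unit_square(self):
        assert cm.centroid_size(SQUARE) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_coincident_points_give_zero(self):
        assert cm.centroid_size(np.ones((5, 3))) == 0.0

    def test_rigid_invariance_and_scaling(self, rng):
        pts = rng.normal(size=(20, 3))
        r = _random_rotation(rng)
        t = rng.normal(size=3) * 50
        base = cm.centroid_size(pts)
        assert cm.centroid_size(pts @ r + t) == pytest.approx(base, abs=1e-9)
        assert cm.centroid_size(3.7 * pts) == pytest.approx(3.7 * base, rel=1e-12)

    def test_non_finite_rejected(self):
        bad = SQUARE.copy()
        bad[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            cm.centroid_size(bad)


class TestPairAlignment:
    def test_similarity_copy_has_zero_distance(self, rng):
        a = rng.normal(size=(12, 3))
        b = 2.5 * a @ _random_rotation(rng) + rng.normal(size=3) * 10
        res = cm.procrustes_align_pair(a, b)
        assert res.distance < 1e-10
        assert np.allclose(res.apply(b), a, atol=1e-9)

    def test_self_alignment_identity(self, rng):
        a = rng.normal(size=(8, 3))
        res = cm.procrustes_align_pair(a, a)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert res.scale == pytest.approx(1.0, abs=1e-12)
        assert res.distance < 1e-12

    def test_distance_matches_numerical_optimizer(self):
        rng = np.random.default_rng(77)
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3))
        d = cm.procrustes_distance(a, b)
        assert d == pytest.approx(pairwise_distance_by_optimizer(a, b), abs=1e-6)

    def test_no_reflection(self, rng):
        a = rng.normal(size=(10, 3))
        b = a.copy()
        b[:, 0] *= -1  # mirrored copy
        res = cm.procrustes_align_pair(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.distance > 0.1  # a mirror image is NOT a similarity copy here

    def test_mismatch_and_degenerate_errors(self, rng):
        with pytest.raises(ShapeMismatchError):
            cm.procrustes_align_pair(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(DegenerateConfigurationError):
            cm.procrustes_align_pair(np.ones((5, 3)), rng.normal(size=(5, 3)))


def _configs(points_list, tooth=cm.Tooth.FP):
    return [
        cm.LandmarkConfiguration(f"s{i}", tooth, p, ["fixed"] * len(p))
        for i, p in enumerate(points_list)
    ]


class TestGeneralizedProcrustes:
    def test_identical_configs_zero_residual(self, rng):
        pts = rng.normal(size=(9, 3))
        out = cm.generalized_procrustes(_configs([pts] * 4))
        assert out.converged
        assert np.allclose(out.aligned, out.mean_shape[None], atol=1e-12)
        assert out.residual_history[-1] < 1e-20

    def test_unit_centroid_size_and_mean_identity(self, rng):
        pts = [rng.normal(size=(9, 3)) for _ in range(6)]
        out = cm.generalized_procrustes(_configs(pts))
        sizes = np.linalg.norm(out.aligned.reshape(6, -1), axis=1)
        assert np.allclose(sizes, 1.0, atol=1e-9)
        mean = out.aligned.mean(axis=0)
        assert np.allclose(mean / np.linalg.norm(mean), out.mean_shape, atol=1e-9)

    def test_rigid_motion_of_all_inputs_is_immaterial(self, rng):
        pts = [rng.normal(size=(7, 3)) for _ in range(5)]
        out1 = cm.generalized_procrustes(_configs(pts))
        r = _random_rotation(rng)
        t = rng.normal(size=3) * 30
        out2 = cm.generalized_procrustes(_configs([p @ r + t for p in pts]))
        d1 = [
            cm.procrustes_distance(out1.aligned[i], out1.aligned[j])
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        d2 = [
            cm.procrustes_distance(out2.aligned[i], out2.aligned[j])
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        assert np.allclose(d1, d2, atol=1e-9)

    def test_two_config_pairwise_decomposition(self, rng):
        """For two nearby shapes, each aligned config sits half the pairwise
        Procrustes distance from the mean."""
        a = rng.normal(size=(15, 3))
        b = a + 1e-3 * rng.normal(size=a.shape)
        pair = cm.procrustes_align_pair(a, b)
        out = cm.generalized_procrustes(_configs([a, b]))
        da = np.linalg.norm(out.aligned[0] - out.mean_shape)
        db = np.linalg.norm(out.aligned[1] - out.mean_shape)
        assert da == pytest.approx(db, abs=1e-8)
        assert da == pytest.approx(pair.distance / 2, abs=1e-8)

    def test_residual_non_increasing(self, rng):
        pts = [rng.normal(size=(10, 3)) for _ in range(8)]
        out = cm.generalized_procrustes(_configs(pts))
        assert np.all(np.diff(out.residual_history) <= 1e-12)

    def test_mixed_teeth_rejected(self, rng):
        a = cm.LandmarkConfiguration("a", cm.Tooth.FP, rng.normal(size=(5, 3)), ["fixed"] * 5)
        b = cm.LandmarkConfiguration("b", cm.Tooth.SP, rng.normal(size=(5, 3)), ["fixed"] * 5)
        with pytest.raises(ShapeMismatchError):
            cm.generalized_procrustes([a, b])

    def test_non_convergence_flag(self, rng):
        pts = [rng.normal(size=(8, 3)) for _ in range(6)]
        out = cm.generalized_procrustes(_configs(pts), tol=1e-16, max_iter=1)
        assert not out.converged
        assert out.iterations_used == 1


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
def test_centroid_size_similarity_properties(seed, scale):
    """Centroid size is rigid-invariant and 1-homogeneous for any shape."""
    r = np.random.default_rng(seed)
    pts = r.normal(size=(6, 3))
    rot = _random_rotation(r)
    base = cm.centroid_size(pts)
    assert cm.centroid_size(scale * pts @ rot + r.normal(size=3)) == pytest.approx(
        scale * base, rel=1e-9, abs=1e-12
    )
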