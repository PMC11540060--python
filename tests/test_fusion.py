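"""Similarity fusion: normalization, KNN affinities, cross-diffusion, merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgjmda import RunConfig
from sgjmda.fusion import (
    cross_diffuse,
    fuse_side,
    knn_affinity,
    knn_count,
    merge_with_functional,
    normalize_full,
    symmetrize,
)
from sgjmda.matrices import SimilarityMatrix
from sgjmda.synthetic import clustered_similarity_views

from conftest import random_symmetric


class TestNormalizeFull:
    def test_hand_computed_row(self):
        # off-diagonals (0.4, 0.6) scale to (0.2, 0.3); diagonal pinned at 1/2
        S = np.array([[1.0, 0.4, 0.6], [0.4, 1.0, 0.5], [0.6, 0.5, 1.0]])
        out = normalize_full(S)
        np.testing.assert_allclose(out[0], [0.5, 0.2, 0.3])

    def test_rows_sum_to_one_and_diagonal_half(self):
        out = normalize_full(random_symmetric(9, seed=4))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_array_equal(np.diag(out), 0.5)

    def test_uniform_offdiagonals_stay_uniform(self):
        S = np.full((5, 5), 0.3)
        np.fill_diagonal(S, 1.0)
        out = normalize_full(S)
        off = out[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.125)

    def test_isolated_row_is_an_error_naming_the_entity(self):
        S = random_symmetric(4, seed=5)
        S[2, :] = S[:, 2] = 0.0
        S[2, 2] = 1.0
        m = SimilarityMatrix(["a", "b", "lonely", "d"], S)
        with pytest.raises(ValueError, match="lonely"):
            normalize_full(m)
        out = normalize_full(m, uniform_row_fallback=True)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)


class TestKnnAffinity:
    def test_hand_computed_row(self):
        S = np.array(
            [
                [1.0, 0.5, 0.3, 0.2],
                [0.5, 1.0, 0.1, 0.1],
                [0.3, 0.1, 1.0, 0.1],
                [0.2, 0.1, 0.1, 1.0],
            ]
        )
        out = knn_affinity(S, 2)
        np.testing.assert_allclose(out[0], [0.0, 0.625, 0.375, 0.0])

    def test_full_neighborhood_limit_matches_offdiagonal_normalization(self):
        S = random_symmetric(6, seed=6)
        out = knn_affinity(S, 5)
        off = S.copy()
        np.fill_diagonal(off, 0.0)
        np.testing.assert_allclose(out, off / off.sum(axis=1, keepdims=True))

    def test_neighbor_count_rule(self):
        assert knn_count(30, 10) == 3
        assert knn_count(1177, 10) == 117
        assert knn_count(7, 10) == 1  # floors at a minimum of one neighbor

    def test_tie_broken_toward_lower_index(self):
        S = np.array([[1.0, 0.4, 0.4, 0.4], [0.4, 1, 0, 0], [0.4, 0, 1, 0], [0.4, 0, 0, 1]])
        out = knn_affinity(S, 2)
        assert out[0, 1] > 0 and out[0, 2] > 0 and out[0, 3] == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 7))
    def test_rows_stochastic_with_exact_support(self, seed, k):
        S = random_symmetric(8, seed=seed)
        out = knn_affinity(S, k)
        assert ((out > 0).sum(axis=1) <= k).all()
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-8)

    def test_self_excluded_and_bad_k_rejected(self):
        S = random_symmetric(5, seed=7)
        assert np.all(np.diag(knn_affinity(S, 2)) == 0.0)
        with pytest.raises(ValueError):
            knn_affinity(S, 5)


class TestCrossDiffuse:
    @staticmethod
    def _setup(n=12, n_clusters=2, seed=0):
        views_raw, clean, labels = clustered_similarity_views(
            n, n_clusters, noise_sd=0.05, seed=seed
        )
        views = [normalize_full(v) for v in views_raw]
        aff = [knn_affinity(v, max(1, n // 4)) for v in views_raw]
        return views, aff, labels

    def test_converges_and_preserves_cluster_structure(self):
        views, aff, labels = self._setup()
        res = cross_diffuse(views, aff, tol=1e-6, max_iter=1000, renormalize=True)
        assert res.converged
        assert np.all(res.residuals[-1] < 1e-6)
        fused = symmetrize(res.fused)
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        within = fused[same].mean()
        between = fused[~same & ~np.eye(len(labels), dtype=bool)].mean()
        assert within > between

    def test_single_step_is_mean_of_once_updated_views(self):
        views, aff, _ = self._setup()
        res = cross_diffuse(views, aff, tol=1e-12, max_iter=1, renormalize=False)
        expected = []
        for k in range(3):
            others = sum(views[j] for j in range(3) if j != k) / 2.0
            expected.append(aff[k] @ others @ aff[k].T)
        np.testing.assert_allclose(res.fused, sum(expected) / 3.0, atol=1e-12)

    def test_updates_are_simultaneous_not_sequential(self):
        # a sequential sweep (view 1 updated before computing view 2's input)
        # must give a different answer on a generic instance
        views, aff, _ = self._setup(seed=3)
        simultaneous = cross_diffuse(
            views, aff, tol=1e-12, max_iter=1, renormalize=False
        ).views
        seq = [v.copy() for v in views]
        for k in range(3):
            others = sum(seq[j] for j in range(3) if j != k) / 2.0
            seq[k] = aff[k] @ others @ aff[k].T
        assert max(
            np.abs(a - b).max() for a, b in zip(simultaneous, seq)
        ) > 1e-6

    def test_without_renormalization_structure_washes_out(self):
        # on a connected affinity graph the plain update contracts toward a
        # constant matrix; per-sweep renormalization preserves structure
        from conftest import random_symmetric

        views_raw = [random_symmetric(12, seed=s) for s in (1, 2, 3)]
        views = [normalize_full(v) for v in views_raw]
        aff = [knn_affinity(v, 6) for v in views_raw]
        flat = cross_diffuse(views, aff, tol=1e-9, max_iter=3000).fused
        assert (flat.max() - flat.min()) / flat.max() < 1e-8
        kept = cross_diffuse(
            views, aff, tol=1e-9, max_iter=3000, renormalize=True
        ).fused
        assert (kept.max() - kept.min()) / kept.max() > 1e-3


class TestSymmetrizeAndMerge:
    def test_symmetrize_formula_and_idempotence(self):
        np.testing.assert_array_equal(
            symmetrize([[0.0, 1.0], [0.0, 0.0]]), [[0.0, 0.5], [0.5, 0.0]]
        )
        M = np.random.default_rng(1).random((5, 5))
        once = symmetrize(M)
        np.testing.assert_array_equal(once, once.T)
        np.testing.assert_array_equal(symmetrize(once), once)

    def test_merge_boundaries_and_default_weight(self):
        SMp = np.full((2, 2), 0.5)
        FS = np.full((2, 2), 0.1)
        np.testing.assert_array_equal(merge_with_functional(SMp, FS, 0.0), FS)
        np.testing.assert_array_equal(merge_with_functional(SMp, FS, 1.0), SMp)
        np.testing.assert_allclose(merge_with_functional(SMp, FS, 0.28), 0.212)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(alpha=st.floats(0.0, 1.0), step=st.floats(0.001, 0.1))
    def test_merge_monotone_in_alpha_where_smp_exceeds_fs(self, alpha, step):
        SMp, FS = np.array([[0.9]]), np.array([[0.2]])
        hi = min(alpha + step, 1.0)
        assert (
            merge_with_functional(SMp, FS, hi)[0, 0]
            >= merge_with_functional(SMp, FS, alpha)[0, 0]
        )


class TestFuseSide:
    def test_planted_clusters_survive_full_pipeline(self):
        views_raw, clean, labels = clustered_similarity_views(30, 3, noise_sd=0.1)
        ids = [f"e{i}" for i in range(30)]
        mats = [SimilarityMatrix(ids, v) for v in views_raw]
        fs = SimilarityMatrix(ids, clean)
        cfg = RunConfig()
        fused = fuse_side(mats[0], mats[1], mats[2], fs, cfg)
        assert fused.ids == ids
        v = fused.values
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        assert v[same].mean() > v[~same & ~np.eye(30, dtype=bool)].mean()
        np.testing.assert_allclose(v, v.T, atol=1e-12)

    def test_deterministic_bitwise(self, bench, small_cfg):
        a = fuse_side(*bench.microbe_similarities, small_cfg)
        b = fuse_side(*bench.microbe_similarities, small_cfg)
        assert np.array_equal(a.values, b.values)

    def test_degenerate_equal_views_stay_finite_symmetric(self):
        base = random_symmetric(10, seed=8)
        ids = [f"e{i}" for i in range(10)]
        m = SimilarityMatrix(ids, base)
        fused = fuse_side(m, m, m, m, RunConfig(alpha=0.5))
        assert np.all(np.isfinite(fused.values))
        np.testing.assert_allclose(fused.values, fused.values.T, atol=1e-12)

    def test_sf_ablation_is_plain_average(self):
        views_raw, clean, _ = clustered_similarity_views(12, 2, noise_sd=0.1)
        ids = [f"e{i}" for i in range(12)]
        mats = [SimilarityMatrix(ids, v) for v in views_raw]
        fs = SimilarityMatrix(ids, clean)
        avg = fuse_side(mats[0], mats[1], mats[2], fs, RunConfig(ablation="SF"))
        expected = (views_raw[0] + views_raw[1] + views_raw[2] + clean) / 4.0
        np.testing.assert_allclose(avg.values, expected, atol=1e-12)
        full = fuse_side(mats[0], mats[1], mats[2], fs, RunConfig())
        assert np.abs(avg.values - full.values).max() > 1e-6
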