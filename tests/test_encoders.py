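"""Graph encoders: propagation operators, hetero graph, JK aggregation."""

import numpy as np
import pytest

from sgjmda import RunConfig
from sgjmda._autodiff import Tensor
from sgjmda.encoders import (
    block_widths,
    build_hetero,
    encode,
    gcn_homogeneous,
    jk_aggregate,
    multi_neighborhood_layer,
    normalized_operator,
)

from conftest import random_symmetric


def neighbor_sum_oracle(P: np.ndarray, H: np.ndarray, power: int) -> np.ndarray:
    """Explicit repeated normalized neighbor-sum: P applied `power` times."""
    out = H.copy()
    for _ in range(power):
        nxt = np.zeros_like(out)
        for i in range(P.shape[0]):
            for j in range(P.shape[1]):
                nxt[i] += P[i, j] * out[j]
        out = nxt
    return out


class TestNormalizedOperator:
    def test_three_node_path_matches_hand_computation(self):
        G = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        P = normalized_operator(G)
        s = 1 / np.sqrt(2)
        np.testing.assert_allclose(P, [[0, s, 0], [s, 0, s], [0, s, 0]])

    def test_isolated_node_rows_are_zero(self):
        G = np.zeros((3, 3))
        G[0, 1] = G[1, 0] = 1.0
        P = normalized_operator(G)
        assert np.all(P[2] == 0) and np.all(P[:, 2] == 0)

    def test_literal_variant_uses_positive_right_exponent(self):
        G = random_symmetric(4, seed=1)
        deg = G.sum(axis=1)
        lit = normalized_operator(G, literal=True)
        np.testing.assert_allclose(
            lit, (deg**-0.5)[:, None] * G * (deg**0.5)[None, :]
        )

    @pytest.mark.parametrize("power", [1, 2, 3, 4])
    def test_powers_match_neighbor_sum_oracle_on_small_graphs(self, power):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = rng.integers(3, 9)
            G = (rng.random((n, n)) < 0.4).astype(float)
            G = np.maximum(G, G.T) + np.eye(n)
            P = normalized_operator(G)
            H = rng.standard_normal((n, 3))
            direct = np.linalg.matrix_power(P, power) @ H
            oracle = neighbor_sum_oracle(P, H, power)
            assert np.abs(direct - oracle).max() < 1e-10


class TestHomogeneousGCN:
    def test_diagonal_graph_propagation_is_identity(self):
        G = np.diag([2.0, 3.0, 4.0])
        out = gcn_homogeneous(G, np.eye(3), activation="linear")
        np.testing.assert_allclose(out.value, normalized_operator(G) @ G)

    def test_identical_rows_give_identical_embeddings(self):
        G = random_symmetric(4, seed=2)
        G[1] = G[0]
        G[:, 1] = G[:, 0]
        G[0, 1] = G[1, 0] = G[0, 0]
        W = np.random.default_rng(3).standard_normal((4, 5))
        out = gcn_homogeneous(G, W).value
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        G = random_symmetric(6, seed=5)
        W_shared = rng.standard_normal((6, 4))
        perm = rng.permutation(6)
        base = gcn_homogeneous(G, W_shared).value
        permuted = gcn_homogeneous(G[np.ix_(perm, perm)], W_shared[perm]).value
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)


class TestHeteroGraph:
    def test_smallest_bipartite_graph(self):
        hg = build_hetero(np.array([[1.0]]), self_loops=False)
        np.testing.assert_array_equal(hg.adjacency, [[0, 1], [1, 0]])

    def test_block_structure_and_symmetry(self):
        A = (np.random.default_rng(6).random((2, 3)) < 0.5).astype(float)
        hg = build_hetero(A)
        G = hg.adjacency
        assert G.shape == (5, 5)
        np.testing.assert_array_equal(G, G.T)
        assert np.all(G[:2, :2] == 0) and np.all(G[2:, 2:] == 0)
        np.testing.assert_array_equal(G[:2, 2:], A)

    def test_empty_graph_propagates_nothing_without_self_loops(self):
        hg = build_hetero(np.zeros((3, 2)), self_loops=False)
        assert np.all(hg.operator == 0.0)


class TestMultiNeighborhood:
    def test_k_zero_is_a_plain_linear_map(self):
        H = np.random.default_rng(7).standard_normal((4, 3))
        W = np.random.default_rng(8).standard_normal((3, 2))
        out = multi_neighborhood_layer(np.eye(4), H, [W], k_max=0)
        np.testing.assert_allclose(out.value, H @ W)

    def test_blocks_equal_explicit_power_oracle(self):
        rng = np.random.default_rng(9)
        A = (rng.random((3, 2)) < 0.6).astype(float)
        hg = build_hetero(A)
        H = rng.standard_normal((5, 4))
        weights = [rng.standard_normal((4, 2)) for _ in range(3)]
        out = multi_neighborhood_layer(hg.operator, H, weights, k_max=2).value
        for i in range(3):
            expected = neighbor_sum_oracle(hg.operator, H, i) @ weights[i]
            np.testing.assert_allclose(out[:, 2 * i : 2 * i + 2], expected, atol=1e-10)

    def test_block_width_split_sums_to_layer_size(self):
        assert block_widths(128, 4) == [28, 25, 25, 25, 25]
        assert sum(block_widths(33, 4)) == 33
        with pytest.raises(ValueError):
            block_widths(3, 4)


class TestJKAggregate:
    def test_selector_and_convexity_cases(self):
        rng = np.random.default_rng(10)
        h1, h2 = rng.standard_normal((3, 2)), rng.standard_normal((3, 2))
        np.testing.assert_allclose(jk_aggregate([h1], [1.0]).value, h1)
        np.testing.assert_allclose(jk_aggregate([h1, h1], [0.5, 0.5]).value, h1)
        np.testing.assert_allclose(jk_aggregate([h1, h2], [1.0, 0.0]).value, h1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jk_aggregate([np.zeros((2, 2)), np.zeros((3, 2))], [0.5, 0.5])


class TestEncode:
    def test_embedding_dims_and_determinism(self, bench, fused):
        SM, SD = fused
        cfg = RunConfig(layer_size=32, seed=11)
        a = encode(bench.associations, SM, SD, cfg)
        b = encode(bench.associations, SM, SD, cfg)
        assert a[0].shape == (120, 32) and a[1].shape == (20, 32)
        assert a[2].shape == (120, 32) and a[3].shape == (20, 32)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_het_ablation_skips_heterogeneous_stage(self, bench, fused):
        SM, SD = fused
        out = encode(bench.associations, SM, SD, RunConfig(layer_size=32, ablation="Het"))
        assert out[2] is None and out[3] is None

    def test_all_zero_associations_still_finite(self, bench, fused):
        SM, SD = fused
        A0 = np.zeros_like(bench.associations.values)
        out = encode(A0, SM, SD, RunConfig(layer_size=32))
        assert all(np.all(np.isfinite(x)) for x in out)

    @pytest.mark.parametrize("alpha", [0.1, 0.4])
    @pytest.mark.parametrize("k", [2, 6])
    def test_finite_over_hyperparameter_grid(self, bench, fused, alpha, k):
        SM, SD = fused
        cfg = RunConfig(layer_size=32, alpha=alpha, k_neighborhood=k, n_hetero_layers=1)
        out = encode(bench.associations, SM, SD, cfg)
        assert all(np.all(np.isfinite(x)) for x in out)
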