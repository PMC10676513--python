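"""Semantic, neighborhood (GAT), and path-view interaction operations."""

import math

import numpy as np
import pytest

from conftest import dense_gat_oracle, kernel_pooling_oracle, random_dag

from termalign import (
    GATConfig,
    GATParams,
    KernelBank,
    attention_coefficients,
    gat_forward,
    kernel_row_features,
    max_pool_interaction,
    neighborhood_interaction,
    path_interaction,
    path_similarity_matrix,
    semantic_interaction,
    semantic_similarity,
)
from termalign.neighborhood import _elu, softmax


class TestSemanticView:
    def test_identity_scale_and_orthogonality(self):
        v = np.array([1.0, 2.0, -3.0])
        assert semantic_similarity(v, v) == pytest.approx(1.0)
        assert semantic_similarity(v, 2 * v) == pytest.approx(1.0)
        assert semantic_similarity(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(Exception, match="zero-norm"):
            semantic_similarity(np.zeros(3), np.ones(3))

    def test_interaction_vector_layout(self):
        h = semantic_interaction(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(h, [1.0, 1.0, 0.0])
        v = np.array([0.5, -0.5, 2.0])
        np.testing.assert_allclose(semantic_interaction(v, v), [0, 0, 0, 1.0])

    def test_interaction_symmetric_under_swap(self):
        rng = np.random.default_rng(0)
        v, w = rng.normal(size=8), rng.normal(size=8)
        np.testing.assert_allclose(semantic_interaction(v, w), semantic_interaction(w, v))

    def test_cosine_matches_dot_norm_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v, w = rng.normal(size=16), rng.normal(size=16)
            oracle = float(sum(a * b for a, b in zip(v, w))) / (
                math.sqrt(sum(a * a for a in v)) * math.sqrt(sum(b * b for b in w))
            )
            assert semantic_similarity(v, w) == pytest.approx(oracle, abs=1e-7)
            assert abs(semantic_similarity(v, w)) <= 1.0 + 1e-12


class TestAttention:
    def _params(self, dim=6, heads=2, seed=0, layers=2):
        cfg = GATConfig(dim=dim, heads=heads, layers=layers)
        return GATParams.init(cfg, np.random.default_rng(seed))

    def test_single_neighbor_gets_weight_one(self):
        params = self._params()
        rng = np.random.default_rng(2)
        alpha = attention_coefficients(params, rng.normal(size=6), rng.normal(size=(1, 6)))
        np.testing.assert_allclose(alpha, np.ones((2, 1)))

    def test_identical_neighbors_share_weight_uniformly(self):
        params = self._params()
        rng = np.random.default_rng(3)
        h_i = rng.normal(size=6)
        nbr = np.tile(rng.normal(size=6), (4, 1))
        alpha = attention_coefficients(params, h_i, nbr)
        np.testing.assert_allclose(alpha, np.full((2, 4), 0.25), atol=1e-12)

    def test_softmax_of_ln2_and_zero(self):
        np.testing.assert_allclose(
            softmax(np.array([math.log(2.0), 0.0])), [2 / 3, 1 / 3], atol=1e-12
        )

    def test_weights_sum_to_one_on_random_graphs(self):
        rng = np.random.default_rng(4)
        params = self._params(dim=5, heads=3)
        for _ in range(50):
            m = int(rng.integers(1, 9))
            alpha = attention_coefficients(params, rng.normal(size=5), rng.normal(size=(m, 5)))
            np.testing.assert_allclose(alpha.sum(axis=1), np.ones(3), atol=1e-6)


class TestGATForward:
    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        cfg = GATConfig(dim=7, heads=2, layers=2)
        for trial in range(10):
            tb = random_dag(rng, max_nodes=15, p=0.3)
            params = GATParams.init(cfg, np.random.default_rng(trial))
            emb = {cid: rng.normal(size=7) for cid in tb.ids()}
            got = gat_forward(params, tb, emb)
            want = dense_gat_oracle(params, tb, emb)
            for cid in tb.ids():
                np.testing.assert_allclose(got[cid], want[cid], atol=1e-5)

    def test_isolated_node_self_loop(self):
        from termalign import Concept, TerminologyBase

        tb = TerminologyBase(concepts={"X": Concept("X", "x")}).validate()
        cfg = GATConfig(dim=4, heads=2, layers=1)
        params = GATParams.init(cfg, np.random.default_rng(0))
        h = np.array([0.3, -0.7, 1.1, 0.0])
        out = gat_forward(params, tb, {"X": h})
        # self-loop: attention over the singleton is 1, so the output is the
        # nonlinearity of the head-averaged transform of the node itself
        expected = _elu((params.weights[0] @ h).mean(axis=0))
        np.testing.assert_allclose(out["X"], expected)

    def test_neighbor_order_invariance(self, diamond_tb):
        cfg = GATConfig(dim=5, heads=2, layers=2)
        params = GATParams.init(cfg, np.random.default_rng(1))
        rng = np.random.default_rng(6)
        emb = {cid: rng.normal(size=5) for cid in diamond_tb.ids()}
        a = gat_forward(params, diamond_tb, emb)
        shuffled = dict(reversed(list(emb.items())))
        b = gat_forward(params, diamond_tb, shuffled)
        for cid in diamond_tb.ids():
            np.testing.assert_array_equal(a[cid], b[cid])

    def test_mean_aggregator_runs_and_differs(self, diamond_tb):
        rng = np.random.default_rng(7)
        emb = {cid: rng.normal(size=5) for cid in diamond_tb.ids()}
        gat = GATParams.init(GATConfig(dim=5, aggregator="gat"), np.random.default_rng(2))
        mean = GATParams.init(GATConfig(dim=5, aggregator="mean"), np.random.default_rng(2))
        a = gat_forward(gat, diamond_tb, emb)
        b = gat_forward(mean, diamond_tb, emb)
        assert any(not np.allclose(a[c], b[c]) for c in diamond_tb.ids())


class TestNeighborhoodInteraction:
    def test_identical_vectors_zero(self):
        z = np.array([1.0, -2.0, 0.5])
        h = neighborhood_interaction(z, z)
        np.testing.assert_allclose(h, np.zeros(4))

    def test_unit_basis_pair(self):
        h = neighborhood_interaction(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        np.testing.assert_allclose(h, [1.0, 1.0, math.sqrt(2)])

    def test_l2_tail_matches_independent_computation(self):
        rng = np.random.default_rng(8)
        z, w = rng.normal(size=300), rng.normal(size=300)
        oracle = math.sqrt(sum((a - b) ** 2 for a, b in zip(z, w)))
        assert neighborhood_interaction(z, w)[-1] == pytest.approx(oracle, abs=1e-9)


class TestPathView:
    def test_identical_single_paths(self):
        e = np.array([[0.3, 0.4, 0.5]])
        S = path_similarity_matrix(e, e)
        np.testing.assert_allclose(S, [[1.0]], atol=1e-12)

    def test_matrix_matches_double_loop(self):
        rng = np.random.default_rng(9)
        A, B = rng.normal(size=(2, 6)), rng.normal(size=(3, 6))
        S = path_similarity_matrix(A, B)
        for i in range(2):
            for j in range(3):
                want = float(A[i] @ B[j]) / (np.linalg.norm(A[i]) * np.linalg.norm(B[j]))
                assert S[i, j] == pytest.approx(want, abs=1e-7)

    def test_swap_transposes(self):
        rng = np.random.default_rng(10)
        A, B = rng.normal(size=(2, 5)), rng.normal(size=(4, 5))
        np.testing.assert_allclose(
            path_similarity_matrix(A, B), path_similarity_matrix(B, A).T
        )

    def test_kernel_row_exact_match_pair(self):
        bank = KernelBank(mus=(0.5,), sigmas=(0.1,))
        assert kernel_row_features(np.array([0.5, 0.5]), bank)[0] == pytest.approx(2.0)

    def test_kernel_row_hand_value(self):
        bank = KernelBank(mus=(0.0,), sigmas=(1.0,))
        got = kernel_row_features(np.array([1.0, 0.0]), bank)[0]
        assert got == pytest.approx(math.exp(-0.5) + 1.0, abs=1e-9)

    def test_kernel_row_decays_far_from_mu(self):
        bank = KernelBank(mus=(0.0,), sigmas=(0.1,))
        got = kernel_row_features(np.full(5, 0.9), bank)[0]
        assert got == pytest.approx(0.0, abs=1e-7)

    def test_kernel_row_bounds_and_monotonicity(self):
        bank = KernelBank(mus=(0.3,), sigmas=(0.2,))
        rng = np.random.default_rng(11)
        for _ in range(20):
            row = rng.uniform(-1, 1, size=6)
            k = kernel_row_features(row, bank)[0]
            assert 0.0 < k <= 6.0
            closer = row + 0.5 * (0.3 - row)  # every entry moved toward mu
            assert kernel_row_features(closer, bank)[0] >= k

    def test_exact_match_single_kernel_gives_zero_vector(self):
        bank = KernelBank(mus=(1.0,), sigmas=(0.001,))
        h3 = path_interaction(np.array([[1.0]]), bank)
        np.testing.assert_allclose(h3, [0.0, 0.0], atol=1e-12)

    def test_empty_path_set_convention(self):
        bank = KernelBank.default()
        np.testing.assert_array_equal(path_interaction(None, bank), np.zeros(2 * bank.K))
        np.testing.assert_array_equal(max_pool_interaction(None), np.zeros(1))

    def test_matches_loop_oracle(self):
        bank = KernelBank.default()
        rng = np.random.default_rng(12)
        S = rng.uniform(-1, 1, size=(3, 4))
        got = path_interaction(S, bank)
        want = kernel_pooling_oracle(S, bank.mus, bank.sigmas)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_transpose_swaps_row_and_column_halves(self):
        bank = KernelBank.default()
        rng = np.random.default_rng(13)
        S = rng.uniform(-1, 1, size=(2, 5))
        a = path_interaction(S, bank)
        b = path_interaction(S.T, bank)
        K = bank.K
        np.testing.assert_array_equal(a[:K], b[K:])
        np.testing.assert_array_equal(a[K:], b[:K])
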