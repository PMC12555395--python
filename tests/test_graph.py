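"""Graph creation block: scoring, kNN selection, edge features, aggregation."""

import numpy as np
import pytest

from gcassn.autodiff import Tensor
from gcassn.graph import (GraphBlockParams, LocalGraphSet, build_local_graph,
                          edge_features, graph_aggregate, knn_graph,
                          neighborhood_score, pairwise_sq_euclidean)

COLLINEAR = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])


def brute_force_knn(F, k):
    """O(N^2) oracle: full sort of definitional squared distances,
    self forced first, ties by ascending index."""
    n = len(F)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        d = [(np.sum((F[j] - F[i]) ** 2), j) for j in range(n) if j != i]
        d.sort()
        out[i] = [i] + [j for _, j in d[:k - 1]]
    return out


class TestNeighborhoodScore:
    def test_sq_euclidean_hand_value(self):
        F = np.array([[1.0, 2.0, 2.0], [0.0, 0.0, 0.0]])
        s = neighborhood_score(F, "sq_euclidean")
        assert s.matrix[0, 1] == pytest.approx(9.0)

    @pytest.mark.parametrize("metric", ["sq_euclidean", "cosine", "pearson",
                                        "weighted"])
    def test_self_score_zero(self, rng, metric):
        F = rng.normal(size=(10, 4))
        s = neighborhood_score(F, metric)
        np.testing.assert_allclose(np.diag(s.matrix), 0.0, atol=1e-12)

    def test_cosine_parallel_vectors(self):
        F = np.array([[1.0, 0.0], [2.0, 0.0]])
        s = neighborhood_score(F, "cosine")
        assert s.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matrix_identity_equals_definitional_sum(self, rng):
        F = rng.normal(size=(30, 5))
        d2 = pairwise_sq_euclidean(F)
        direct = ((F[:, None, :] - F[None, :, :]) ** 2).sum(-1)
        np.testing.assert_allclose(d2, direct, atol=1e-6)
        np.testing.assert_allclose(d2, d2.T, atol=1e-12)
        assert d2.min() >= 0

    def test_zero_norm_row_cosine_fallback_no_nan(self):
        F = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        s = neighborhood_score(F, "cosine")
        assert np.all(np.isfinite(s.matrix))
        assert s.matrix[0, 1] == pytest.approx(1.0)
        assert s.matrix[0, 0] == 0.0

    def test_zero_variance_row_pearson_fallback_no_nan(self):
        F = np.array([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0], [0.0, 1.0, 5.0]])
        s = neighborhood_score(F, "pearson")
        assert np.all(np.isfinite(s.matrix))
        assert s.matrix[0, 1] == pytest.approx(1.0)

    def test_weighted_requires_unit_interval_weight(self, rng):
        with pytest.raises(ValueError):
            neighborhood_score(rng.normal(size=(4, 3)), "weighted",
                               weight_sq_euclid=1.5)


class TestKnnGraph:
    def test_collinear_example(self):
        s = neighborhood_score(COLLINEAR)
        idx = knn_graph(s, 2)
        np.testing.assert_array_equal(idx[2], [2, 1])   # d2=1 beats d2=4

    def test_k_one_is_self(self, rng):
        idx = knn_graph(neighborhood_score(rng.normal(size=(7, 3))), 1)
        np.testing.assert_array_equal(idx[:, 0], np.arange(7))

    def test_tie_break_lowest_index(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0]])
        idx = knn_graph(neighborhood_score(pts), 2)
        np.testing.assert_array_equal(idx[0], [0, 1])

    def test_invalid_k_rejected(self, rng):
        s = neighborhood_score(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            knn_graph(s, 6)
        with pytest.raises(ValueError):
            knn_graph(s, 0)

    @pytest.mark.parametrize("c", [3, 64])
    @pytest.mark.parametrize("k", [1, 5, 30])
    def test_agrees_with_brute_force_oracle(self, c, k):
        rng = np.random.default_rng(100 * c + k)
        for _ in range(5):
            F = rng.normal(size=(60, c))
            idx = knn_graph(neighborhood_score(F), k)
            np.testing.assert_array_equal(idx, brute_force_knn(F, k))

    def test_neighbor_sets_nested_in_k(self, rng):
        F = rng.normal(size=(50, 3))
        s = neighborhood_score(F)
        small = knn_graph(s, 5)
        large = knn_graph(s, 20)
        for i in range(50):
            assert set(small[i]) <= set(large[i])
            np.testing.assert_array_equal(small[i], large[i, :5])


class TestEdgeFeatures:
    def test_componentwise_difference(self):
        F = np.array([[1.0, 1, 1], [2.0, 3, 1]])
        e = edge_features(F, np.array([[0, 1], [1, 0]]))
        np.testing.assert_array_equal(e[0, 1], [1, 2, 0])

    def test_self_edge_is_zero(self, rng):
        F = rng.normal(size=(6, 4))
        idx = knn_graph(neighborhood_score(F), 3)
        e = edge_features(F, idx)
        np.testing.assert_allclose(e[:, 0], 0.0, atol=1e-12)

    def test_translation_invariance(self, rng):
        F = rng.normal(size=(8, 3))
        idx = knn_graph(neighborhood_score(F), 4)
        shifted = edge_features(F + np.array([5.0, -2.0, 1.0]), idx)
        np.testing.assert_allclose(shifted, edge_features(F, idx), atol=1e-12)

    def test_out_of_range_index_rejected(self, rng):
        with pytest.raises(IndexError):
            edge_features(rng.normal(size=(4, 3)), np.array([[0, 9]]))


def _fixed_params(projector: str) -> GraphBlockParams:
    """Bare (unnormalized) block with conv frozen to a simple projector."""
    params = GraphBlockParams(3, 3, np.random.default_rng(0), normalize=False)
    w = np.zeros((6, 3))
    if projector == "edge":
        w[3:, :] = np.eye(3)
    elif projector == "center":
        w[:3, :] = np.eye(3)
    params.conv.weight.data = w
    params.conv.bias.data = np.zeros(3)
    return params


class TestGraphAggregate:
    def test_edge_projector_hand_value(self):
        # row 2 of the collinear cloud, k=2: edges {0, (-1,0,0)};
        # relu then elementwise max gives the zero vector
        graph = build_local_graph(COLLINEAR, 2)
        out = graph_aggregate(COLLINEAR, graph, _fixed_params("edge"))
        np.testing.assert_allclose(out[2], [0.0, 0.0, 0.0], atol=1e-12)

    def test_center_projector_returns_relu_features(self, rng):
        F = rng.normal(size=(10, 3))
        graph = build_local_graph(F, 4)
        out = graph_aggregate(F, graph, _fixed_params("center"))
        np.testing.assert_allclose(out, np.maximum(F, 0.0), atol=1e-12)

    def test_invariant_to_neighbor_order(self, rng):
        F = rng.normal(size=(12, 3))
        params = GraphBlockParams(3, 8, rng, normalize=False)
        graph = build_local_graph(F, 5)
        out = graph_aggregate(F, graph, params)
        perm = np.arange(5)
        perm[1:] = perm[1:][::-1]         # reorder the true neighbors
        shuffled = LocalGraphSet(graph.neighbor_idx[:, perm],
                                 edge_features(F, graph.neighbor_idx[:, perm]),
                                 5)
        np.testing.assert_allclose(graph_aggregate(F, shuffled, params), out,
                                   atol=1e-12)

    def test_matches_per_point_loop_definition(self, rng):
        """Batched implementation equals the definitional per-point loop."""
        F = rng.normal(size=(9, 4))
        params = GraphBlockParams(4, 6, rng, normalize=False)
        graph = build_local_graph(F, 3)
        out = graph_aggregate(F, graph, params)
        W, b = params.conv.weight.data, params.conv.bias.data
        for i in range(9):
            rows = [np.concatenate([F[i], F[j] - F[i]])
                    for j in graph.neighbor_idx[i]]
            expect = np.max(np.maximum(np.array(rows) @ W + b, 0.0), axis=0)
            np.testing.assert_allclose(out[i], expect, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        F = rng.normal(size=(15, 3))
        params = GraphBlockParams(3, 8, rng, normalize=False)
        out = graph_aggregate(F, build_local_graph(F, 4), params)
        perm = rng.permutation(15)
        out_p = graph_aggregate(F[perm], build_local_graph(F[perm], 4), params)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-5)

    def test_dimension_mismatch_rejected(self, rng):
        F = rng.normal(size=(6, 3))
        params = GraphBlockParams(5, 4, rng)
        with pytest.raises(ValueError):
            graph_aggregate(F, build_local_graph(F, 2), params)

    def test_gradients_flow_through_edges_and_centers(self, rng):
        F = Tensor(rng.normal(size=(7, 3)), requires_grad=True)
        params = GraphBlockParams(3, 4, rng, normalize=False)
        graph = build_local_graph(F, 3)
        graph_aggregate(F, graph, params).sum().backward()
        assert F.grad is not None and np.linalg.norm(F.grad) > 0
        assert np.linalg.norm(params.conv.weight.grad) > 0
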