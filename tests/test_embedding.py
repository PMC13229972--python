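"""Tests of the Isomap/PCA embedding machinery and its quality metrics."""

import numpy as np
import pytest

from eeglrtc import (
    classical_mds,
    elbow_dimension,
    explained_variance,
    geodesic_distances,
    isomap_embed,
    knn_adjacency,
    pairwise_euclidean,
    pca_embed,
    select_k,
    trustworthiness,
)


class TestPairwiseEuclidean:
    def test_three_four_five(self):
        D = pairwise_euclidean(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, rng):
        D = pairwise_euclidean(rng.normal(0, 1, (20, 4)))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_duplicate_rows_have_zero_distance(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
        assert pairwise_euclidean(X)[0, 1] == 0.0

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pairwise_euclidean(np.ones((1, 3)))


class TestKnnAdjacency:
    def test_or_rule_on_line_points(self):
        # points 0, 1, 3 on a line; k=1: 3's nearest is 1, OR symmetrizes
        D = pairwise_euclidean(np.array([[0.0], [1.0], [3.0]]))
        g = knn_adjacency(D, k=1)
        finite = np.isfinite(g.weights)
        np.fill_diagonal(finite, False)
        expected = np.zeros((3, 3), dtype=bool)
        expected[0, 1] = expected[1, 0] = True
        expected[1, 2] = expected[2, 1] = True
        assert np.array_equal(finite, expected)

    def test_full_k_gives_complete_graph(self, rng):
        D = pairwise_euclidean(rng.normal(0, 1, (10, 3)))
        g = knn_adjacency(D, k=9)
        off_diag = ~np.eye(10, dtype=bool)
        assert np.all(np.isfinite(g.weights[off_diag]))

    def test_finiteness_pattern_is_symmetric(self, rng):
        D = pairwise_euclidean(rng.normal(0, 1, (25, 5)))
        g = knn_adjacency(D, k=3)
        assert np.array_equal(np.isfinite(g.weights), np.isfinite(g.weights.T))

    def test_k_out_of_range_rejected(self, rng):
        D = pairwise_euclidean(rng.normal(0, 1, (5, 2)))
        for k in (0, 5):
            with pytest.raises(ValueError):
                knn_adjacency(D, k)


def _bfs_connected(weights):
    """Independent connectivity check by breadth-first search."""
    n = weights.shape[0]
    adj = np.isfinite(weights)
    np.fill_diagonal(adj, False)
    seen = {0}
    frontier = [0]
    while frontier:
        nxt = []
        for i in frontier:
            for j in np.flatnonzero(adj[i]):
                if j not in seen:
                    seen.add(j)
                    nxt.append(j)
        frontier = nxt
    return len(seen) == n


class TestSelectK:
    def test_connected_cloud_returns_sqrt_n_start(self, rng):
        X = rng.normal(0, 1, (90, 3))
        D = pairwise_euclidean(X)
        k = select_k(D)
        assert k == 10  # ceil(sqrt(90)); dense Gaussian cloud connects at k0
        assert _bfs_connected(knn_adjacency(D, k).weights)

    def test_two_cluster_instance_returns_minimal_connecting_k(self, rng):
        a = rng.normal(0, 0.1, (15, 2))
        b = rng.normal(0, 0.1, (15, 2)) + np.array([50.0, 0.0])
        D = pairwise_euclidean(np.vstack([a, b]))
        k0 = int(np.ceil(np.sqrt(30)))
        k = select_k(D)
        assert k > k0
        assert _bfs_connected(knn_adjacency(D, k).weights)
        assert not _bfs_connected(knn_adjacency(D, k - 1).weights)

    def test_four_mutual_neighbors(self):
        D = pairwise_euclidean(np.array([[0.0], [1.0], [2.0], [3.0]]))
        assert select_k(D) == 2


class TestGeodesicDistances:
    def test_path_graph_sums_edges(self):
        W = np.full((3, 3), np.inf)
        np.fill_diagonal(W, 0.0)
        W[0, 1] = W[1, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        from eeglrtc import NeighborGraph

        G = geodesic_distances(NeighborGraph(weights=W, k=1))
        assert G[0, 2] == pytest.approx(2.0)

    def test_geodesic_at_least_euclidean(self, rng):
        X = rng.normal(0, 1, (40, 3))
        D = pairwise_euclidean(X)
        G = geodesic_distances(knn_adjacency(D, 5))
        assert np.all(G >= D - 1e-10)

    def test_complete_graph_equals_euclidean(self, rng):
        X = rng.normal(0, 1, (15, 3))
        D = pairwise_euclidean(X)
        G = geodesic_distances(knn_adjacency(D, 14))
        assert np.allclose(G, D)

    def test_disconnected_graph_raises(self):
        W = np.full((4, 4), np.inf)
        np.fill_diagonal(W, 0.0)
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        from eeglrtc import NeighborGraph

        with pytest.raises(ValueError, match="k"):
            geodesic_distances(NeighborGraph(weights=W, k=1))


class TestClassicalMds:
    def test_collinear_points_recovered_in_1d(self):
        X = np.array([[0.0], [1.0], [2.5], [7.0]])
        G = pairwise_euclidean(X)
        emb = classical_mds(G, d=1)
        assert np.allclose(pairwise_euclidean(emb.coords), G, atol=1e-8)

    def test_euclidean_configuration_is_exact_at_full_rank(self, rng):
        X = rng.normal(0, 1, (12, 4))
        G = pairwise_euclidean(X)
        emb = classical_mds(G, d=4)
        assert np.allclose(pairwise_euclidean(emb.coords), G, atol=1e-8)

    def test_coordinate_columns_square_to_eigenvalues(self, rng):
        G = pairwise_euclidean(rng.normal(0, 1, (10, 3)))
        emb = classical_mds(G, d=3)
        norms_sq = np.sum(emb.coords**2, axis=0)
        assert np.allclose(norms_sq, emb.eigenvalues[:3], atol=1e-8)

    def test_d_beyond_positive_eigenvalues_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])  # rank-1 configuration
        G = pairwise_euclidean(X)
        with pytest.raises(ValueError, match="max usable"):
            classical_mds(G, d=3)


class TestPcaEmbed:
    def test_planar_data_fully_explained_by_two_components(self, rng):
        basis = rng.normal(0, 1, (2, 10))
        X = rng.normal(0, 1, (50, 2)) @ basis
        emb = pca_embed(X, d=2)
        assert explained_variance(emb.eigenvalues, 2) == pytest.approx(100.0)

    def test_scores_are_column_centered(self, rng):
        emb = pca_embed(rng.normal(5, 2, (30, 6)), d=3)
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-10)

    def test_spectrum_invariant_under_orthonormal_rotation(self, rng):
        X = rng.normal(0, 1, (40, 5))
        Q, _ = np.linalg.qr(rng.normal(0, 1, (5, 5)))
        a = pca_embed(X, d=2).eigenvalues
        b = pca_embed(X @ Q, d=2).eigenvalues
        assert np.allclose(a, b, atol=1e-8)

    def test_d_beyond_columns_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_embed(rng.normal(0, 1, (10, 3)), d=4)


class TestElbowDimension:
    def test_clear_elbow_after_third_eigenvalue(self):
        res = elbow_dimension(np.array([10.0, 5.0, 2.0, 0.50, 0.45, 0.40]))
        assert res.dimension == 3
        assert res.clear

    def test_dominant_first_eigenvalue(self):
        res = elbow_dimension(np.array([10.0, 0.1, 0.09, 0.08]))
        assert res.dimension == 1
        assert res.clear

    def test_geometric_decay_flags_no_elbow(self):
        lam = 10.0 * 0.5 ** np.arange(8)
        res = elbow_dimension(lam, default=3)
        assert not res.clear
        assert res.dimension == 3

    def test_too_few_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            elbow_dimension(np.array([3.0, 1.0]))


class TestTrustworthiness:
    def test_identity_embedding_is_perfect(self, rng):
        X = rng.normal(0, 1, (40, 5))
        assert trustworthiness(X, X, n_neighbors=5) == pytest.approx(1.0)

    def test_row_permutation_scores_below_identity(self, rng):
        X = rng.normal(0, 1, (40, 5))
        scores = []
        for s in range(20):
            perm = np.random.default_rng(s).permutation(40)
            scores.append(trustworthiness(X, X[perm], n_neighbors=5))
        assert np.mean(scores) < 1.0
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_matches_reference_implementation(self, rng):
        from sklearn.manifold import trustworthiness as sk_trust

        X = rng.normal(0, 1, (50, 6))
        Y = rng.normal(0, 1, (50, 2))
        for kt in (5, 7):
            assert trustworthiness(X, Y, n_neighbors=kt) == pytest.approx(
                sk_trust(X, Y, n_neighbors=kt), abs=1e-10
            )

    def test_large_neighborhood_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        with pytest.raises(ValueError):
            trustworthiness(X, X, n_neighbors=5)


class TestExplainedVariance:
    def test_three_to_one_split(self):
        assert explained_variance(np.array([3.0, 1.0]), 1) == pytest.approx(75.0)

    def test_all_positive_components_give_total(self):
        assert explained_variance(np.array([4.0, 2.0, 1.0]), 3) == pytest.approx(100.0)

    def test_negative_eigenvalues_excluded_from_denominator(self):
        with_neg = explained_variance(np.array([3.0, 1.0, -0.5, -2.0]), 1)
        without = explained_variance(np.array([3.0, 1.0]), 1)
        assert with_neg == pytest.approx(without)


class TestIsomapAgainstReference:
    def test_coordinates_match_sklearn_up_to_sign(self, rng):
        from sklearn.manifold import Isomap

        X = rng.normal(0, 1, (60, 5))
        k, d = 8, 3
        mine = isomap_embed(X, d=d, k=k).coords
        ref = Isomap(n_neighbors=k, n_components=d).fit_transform(X)
        for j in range(d):
            if np.dot(mine[:, j], ref[:, j]) < 0:
                ref[:, j] *= -1
        assert np.allclose(mine, ref, atol=1e-6)

    def test_isomap_beats_pca_on_curved_manifold(self):
        """Geodesic structure of a swiss-roll-style manifold is preserved
        better (lower residual distance distortion) by Isomap than by PCA at
        the same dimensionality."""
        from sklearn.datasets import make_swiss_roll

        X, _ = make_swiss_roll(n_samples=300, noise=0.05, random_state=0)
        D = pairwise_euclidean(X)
        G = geodesic_distances(knn_adjacency(D, select_k(D)))
        triu = np.triu_indices_from(G, 1)

        def residual(coords):
            DE = pairwise_euclidean(coords)
            return 1.0 - np.corrcoef(G[triu], DE[triu])[0, 1] ** 2

        iso = residual(isomap_embed(X, d=2).coords)
        lin = residual(pca_embed(X, d=2).coords)
        assert iso < lin
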