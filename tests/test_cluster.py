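"""Spectral clustering primitives: kernel, Laplacian, eigengap, embedding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shocktraj import (ClusterParams, affinity_matrix, eigengap_select_k,
                       graph_laplacian, kmeans_cluster, normalized_cut,
                       order_clusters_by_outcome, spectral_clustering,
                       spectral_embed)
from shocktraj.cluster import min_ncut_bipartition, spectral_decomposition
from shocktraj.exceptions import ConfigError, InputError

RAW = ClusterParams(distance_scaling="none", sigma=1.0)


def blobs(rng, centers, n_per, d=13, sd=0.05):
    rows = [c + rng.normal(0, sd, (n_per, d)) for c in
            [np.full(d, c) for c in centers]]
    return np.vstack(rows)


class TestAffinity:
    def test_printed_kernel_value_at_unit_distance(self):
        X = np.zeros((2, 13))
        X[1, 0] = 1.0  # Euclidean distance exactly 1
        W = affinity_matrix(X, RAW)
        assert W[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_zero_distance_gives_unit_weight(self):
        W = affinity_matrix(np.zeros((3, 5)), RAW)
        np.testing.assert_allclose(W, 1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetric_unit_diagonal_on_random_inputs(self, seed):
        X = np.random.default_rng(seed).normal(size=(20, 13))
        for scaling in ("none", "median_pairwise", "median_knn"):
            W = affinity_matrix(X, ClusterParams(distance_scaling=scaling))
            np.testing.assert_array_equal(W, W.T)
            np.testing.assert_allclose(np.diag(W), 1.0)
            assert (W >= 0).all() and (W <= 1).all()

    def test_non_finite_input_rejected(self):
        X = np.zeros((3, 4))
        X[0, 0] = np.nan
        with pytest.raises(InputError):
            affinity_matrix(X)


class TestLaplacian:
    def test_unnormalized_rows_sum_to_zero(self):
        X = np.random.default_rng(0).normal(size=(15, 6))
        L = graph_laplacian(affinity_matrix(X), "unnormalized")
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-10)

    def test_positive_semidefinite(self):
        X = np.random.default_rng(1).normal(size=(25, 6))
        for variant in ("unnormalized", "sym_normalized"):
            L = graph_laplacian(affinity_matrix(X), variant)
            vals = spectral_decomposition(L).eigenvalues
            assert vals[0] >= -1e-10

    def test_component_count_equals_zero_eigenvalue_multiplicity(self):
        # two duplicate-pair blocks with no cross affinity
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        np.fill_diagonal(W, 1.0)
        vals = spectral_decomposition(graph_laplacian(W, "sym_normalized"))
        assert (np.abs(vals.eigenvalues) < 1e-10).sum() == 2

    def test_isolated_node_rejected(self):
        W = np.eye(3) * 0.0
        with pytest.raises(InputError):
            graph_laplacian(W, "unnormalized")


class TestEigengap:
    def test_largest_gap_position(self):
        vals = np.array([0.0, 0.01, 0.02, 0.9, 0.95])
        assert eigengap_select_k(vals, k_max=4) == 3

    def test_equispaced_spectrum_ties_to_smallest_k(self):
        vals = np.linspace(0.0, 1.0, 9)
        assert eigengap_select_k(vals, k_max=8) == 2

    def test_three_components_select_three(self):
        rng = np.random.default_rng(3)
        X = blobs(rng, [0.0, 5.0, 10.0], 12)
        W = affinity_matrix(X, RAW)
        L = graph_laplacian(W, "sym_normalized")
        decomp = spectral_decomposition(L)
        assert eigengap_select_k(decomp, k_max=6) == 3

    def test_k_max_exceeding_size_is_an_error(self):
        with pytest.raises(InputError):
            eigengap_select_k(np.array([0.0, 0.5]), k_max=4)


class TestEmbedding:
    def test_eigenpair_residuals(self):
        X = np.random.default_rng(4).normal(size=(30, 8))
        L = graph_laplacian(affinity_matrix(X), "unnormalized")
        d = spectral_decomposition(L)
        for i in range(5):
            res = L @ d.eigenvectors[:, i] - d.eigenvalues[i] * d.eigenvectors[:, i]
            assert np.linalg.norm(res) < 1e-8

    def test_duplicate_rows_map_to_identical_embeddings(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        X[3] = X[0]
        L = graph_laplacian(affinity_matrix(X), "sym_normalized")
        emb = spectral_embed(L, 2)
        np.testing.assert_allclose(emb[0], emb[3], atol=1e-8)

    def test_components_collapse_to_points_in_embedding(self):
        rng = np.random.default_rng(6)
        X = blobs(rng, [0.0, 8.0, 16.0], 10, sd=0.01)
        L = graph_laplacian(affinity_matrix(X, ClusterParams()), "sym_normalized")
        emb = spectral_embed(L, 3)
        for c in range(3):
            rows = emb[c * 10:(c + 1) * 10]
            assert np.linalg.norm(rows - rows.mean(axis=0), axis=1).max() < 1e-3


class TestKmeansAndPipeline:
    def test_far_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(7)
        emb = np.vstack([np.zeros((10, 2)), np.ones((10, 2))])
        labels = kmeans_cluster(emb + rng.normal(0, 0.01, emb.shape), 2, 10, 0)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_restart_count_irrelevant_on_well_separated_data(self):
        rng = np.random.default_rng(8)
        emb = blobs(rng, [0.0, 3.0, 6.0], 15, d=3, sd=0.05)
        a = kmeans_cluster(emb, 3, restarts=1, seed=0)
        b = kmeans_cluster(emb, 3, restarts=50, seed=0)

        def wss(lbl):
            return sum(((emb[lbl == c] - emb[lbl == c].mean(0)) ** 2).sum()
                       for c in set(lbl))
        assert wss(a) == pytest.approx(wss(b), rel=1e-9)

    def test_same_seed_identical_assignments(self):
        emb = np.random.default_rng(9).normal(size=(40, 3))
        a = kmeans_cluster(emb, 4, 10, seed=5)
        b = kmeans_cluster(emb, 4, 10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_three_archetypes_recovered_end_to_end(self):
        rng = np.random.default_rng(10)
        X = blobs(rng, [0.1, 0.5, 0.9], 100, sd=0.02)
        result = spectral_clustering(X, ClusterParams(seed=0))
        assert result.k == 3
        truth = np.repeat([0, 1, 2], 100)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, result.assignments) == 1.0

    def test_partition_invariant_to_row_permutation(self):
        rng = np.random.default_rng(11)
        X = blobs(rng, [0.0, 1.0], 20, sd=0.05)
        perm = rng.permutation(len(X))
        a = spectral_clustering(X, ClusterParams(seed=1)).assignments
        b = spectral_clustering(X[perm], ClusterParams(seed=1)).assignments
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_partition_invariant_to_uniform_translation(self):
        rng = np.random.default_rng(12)
        X = blobs(rng, [0.0, 1.0, 2.0], 15, sd=0.05)
        a = spectral_clustering(X, ClusterParams(seed=2)).assignments
        b = spectral_clustering(X + 7.3, ClusterParams(seed=2)).assignments
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a, b) == 1.0

    def test_degenerate_single_point_ties_to_min_k(self):
        X = np.full((40, 13), 0.5)
        result = spectral_clustering(X, ClusterParams(seed=3))
        assert result.k == 2  # exactly tied gaps resolve to the smallest k

    def test_single_blob_flagged_low_confidence(self):
        rng = np.random.default_rng(13)
        X = rng.normal(0.5, 0.001, size=(60, 13))
        result = spectral_clustering(X, ClusterParams(seed=3))
        assert result.low_confidence

    def test_cross_check_against_sklearn_spectral(self):
        """Independent implementation agrees on well-separated data."""
        from sklearn.cluster import SpectralClustering
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(14)
        X = blobs(rng, [0.0, 1.0, 2.0], 30, sd=0.03)
        ours = spectral_clustering(X, ClusterParams(seed=0), k=3).assignments
        ref = SpectralClustering(n_clusters=3, affinity="rbf", gamma=10.0,
                                 random_state=0).fit_predict(X)
        assert adjusted_rand_score(ours, ref) == 1.0


class TestOrdering:
    def test_descending_prevalence(self):
        from shocktraj.cluster import ClusterResult
        res = ClusterResult(k=2, assignments=np.array([0, 0, 1, 1, 1]),
                            patient_ids=list("abcde"), decomposition=None,
                            params=ClusterParams())
        flags = [False, True, True, True, False]  # prev a,b:0.5 ; c,d,e:0.67
        ordered = order_clusters_by_outcome(res, flags)
        assert ordered.assignments.tolist() == [2, 2, 1, 1, 1]
        assert ordered.prevalence[1] == pytest.approx(2 / 3)

    def test_tie_broken_by_larger_cluster(self):
        from shocktraj.cluster import ClusterResult
        assign = np.array([0] * 10 + [1] * 4)
        flags = [True] * 5 + [False] * 5 + [True, True, False, False]
        res = ClusterResult(k=2, assignments=assign, patient_ids=[str(i) for i in
                            range(14)], decomposition=None, params=ClusterParams())
        ordered = order_clusters_by_outcome(res, flags)
        # both clusters at 50% shock: the larger one takes the lower number
        assert ordered.assignments[0] == 1 and ordered.assignments[10] == 2

    def test_single_cluster_identity(self):
        from shocktraj.cluster import ClusterResult
        res = ClusterResult(k=1, assignments=np.zeros(4, dtype=int),
                            patient_ids=list("abcd"), decomposition=None,
                            params=ClusterParams())
        ordered = order_clusters_by_outcome(res, [True, False, True, False])
        assert set(ordered.assignments) == {1}


class TestNormalizedCut:
    def test_exhaustive_minimum_on_obvious_split(self):
        rng = np.random.default_rng(15)
        X = blobs(rng, [0.0, 5.0], 4, d=3, sd=0.05)
        W = affinity_matrix(X, RAW)
        best, labels = min_ncut_bipartition(W)
        assert set(labels[:4]) != set(labels[4:])
        assert best <= normalized_cut(W, np.array([0, 1] * 4))

    def test_spectral_bipartition_near_optimal_on_random_data(self):
        rng = np.random.default_rng(16)
        ok = 0
        for _ in range(10):
            X = rng.normal(size=(8, 13))
            params = ClusterParams(seed=0)
            W = affinity_matrix(X, params)
            res = spectral_clustering(X, params, k=2)
            val = normalized_cut(W, res.assignments)
            best, _ = min_ncut_bipartition(W)
            ok += val <= 1.10 * best + 1e-12
        assert ok >= 9
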