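import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cdfcd import (
    WeightMatrix,
    build_weight_matrix,
    estimate_num_clusters,
    hierarchical_cluster,
    linkage_dissimilarity,
    pca_subspace_cluster,
    select_representatives,
    spectral_cluster,
    spectral_embed,
    symmetric_laplacian,
)
from cdfcd.clustering import ClusterAssignment


class TestLinkage:
    def test_single_pair_both_modes(self):
        Ci, Cj = np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])
        assert linkage_dissimilarity(Ci, Cj, "single") == 5.0
        assert linkage_dissimilarity(Ci, Cj, "complete") == 5.0

    def test_cross_pair_enumeration(self):
        Ci = np.array([[0.0, 0.0], [1.0, 0.0]])
        Cj = np.array([[4.0, 0.0]])
        assert linkage_dissimilarity(Ci, Cj, "single") == 3.0
        assert linkage_dissimilarity(Ci, Cj, "complete") == 4.0

    def test_coincident_sets_single_is_zero(self):
        C = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert linkage_dissimilarity(C, C, "single") == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            linkage_dissimilarity(np.empty((0, 2)), np.array([[0.0, 0.0]]))


class TestHierarchical:
    def test_far_singletons_stay_separate(self):
        X = np.array([[0.0], [100.0], [200.0]])
        a = hierarchical_cluster(X, K=3)
        assert len(set(a.labels)) == 3

    def test_hand_agglomeration_1d(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0]])
        a = hierarchical_cluster(X, K=2, mode="single")
        assert a.labels[0] == a.labels[1] == a.labels[2]
        assert a.labels[3] != a.labels[0]

    def test_duplicates_co_clustered(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        for K in (2, 3):
            a = hierarchical_cluster(X, K=K, mode="complete")
            assert a.labels[0] == a.labels[1]

    def test_partition_invariant_under_row_permutation(self, rng):
        X = rng.standard_normal((30, 3))
        a = hierarchical_cluster(X, K=4, mode="complete")
        perm = rng.permutation(30)
        b = hierarchical_cluster(X[perm], K=4, mode="complete")
        # compare partitions as label co-occurrence
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


class TestWeightsAndLaplacian:
    def test_identical_points_weight_one(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]])
        wm = build_weight_matrix(X, sigma=1.0)
        assert wm.W[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(wm.W) == 0)

    def test_kernel_value_at_sigma_sqrt2(self):
        X = np.array([[0.0], [np.sqrt(2.0)]])
        wm = build_weight_matrix(X, sigma=1.0)
        assert wm.W[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_median_sigma_rule(self):
        # pairwise distances of {0, 1, 10} are {1, 9, 10}; median = 9
        wm = build_weight_matrix(np.array([[0.0], [1.0], [10.0]]), sigma="median")
        assert wm.sigma == 9.0

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            build_weight_matrix(np.zeros((4, 2)), sigma="median")

    def test_two_node_laplacian_closed_form(self):
        wm = WeightMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), sigma=1.0)
        bundle = symmetric_laplacian(wm)
        assert np.allclose(bundle.L_sym, [[1.0, -1.0], [-1.0, 1.0]])
        assert np.allclose(bundle.eigvals, [0.0, 2.0], atol=1e-12)

    def test_block_diagonal_zero_multiplicity(self, rng):
        blocks = [np.ones((4, 4)) - np.eye(4) for _ in range(3)]
        W = np.zeros((12, 12))
        for i, b in enumerate(blocks):
            W[4 * i : 4 * i + 4, 4 * i : 4 * i + 4] = b
        bundle = symmetric_laplacian(WeightMatrix(W, 1.0))
        assert np.sum(np.abs(bundle.eigvals) < 1e-8) == 3

    def test_eigenvalue_range(self, rng):
        X = rng.standard_normal((25, 4))
        bundle = symmetric_laplacian(build_weight_matrix(X, sigma=1.0))
        assert bundle.eigvals[0] > -1e-8
        assert bundle.eigvals[-1] < 2 + 1e-8

    def test_isolated_node_named(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        with pytest.raises(ValueError, match="2"):
            symmetric_laplacian(WeightMatrix(W, 1.0))


class TestEigengap:
    @pytest.mark.parametrize(
        "eigvals,expected",
        [
            ((0.0, 0.05, 0.8, 1.0), 2),
            ((0.0, 0.01, 0.02, 0.9, 1.1), 3),
            ((0.0, 1.0), 1),
        ],
    )
    def test_examples(self, eigvals, expected):
        assert estimate_num_clusters(np.array(eigvals)) == expected

    def test_first_maximal_gap_wins_ties(self):
        assert estimate_num_clusters(np.array([0.0, 0.5, 1.0])) == 1


class TestSpectral:
    def test_embedding_rows_unit_or_zero(self, rng):
        X = rng.standard_normal((20, 3))
        bundle = symmetric_laplacian(build_weight_matrix(X, sigma=1.0))
        V = spectral_embed(bundle, 3)
        norms = np.linalg.norm(V, axis=1)
        assert np.all((np.abs(norms - 1) < 1e-9) | (norms < 1e-12))

    def test_disconnected_cliques_two_embedding_values(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 1 - np.eye(4)
        W[4:, 4:] = 1 - np.eye(4)
        V = spectral_embed(symmetric_laplacian(WeightMatrix(W, 1.0)), 2)
        rounded = {tuple(np.round(np.abs(r), 6)) for r in V}
        assert len(rounded) == 2

    def test_two_blobs_eigengap_and_exact_partition(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal((20, 0), 1, (30, 2))])
        truth = np.repeat([0, 1], 30)
        a = spectral_cluster(X, K="auto", seed=0)
        assert a.K == 2
        assert adjusted_rand_score(truth, a.labels) == 1.0

    def test_three_blobs_full_agreement(self, rng):
        X = np.vstack(
            [rng.normal(c, 0.5, (20, 2)) for c in [(0, 0), (15, 0), (0, 15)]]
        )
        a = spectral_cluster(X, K="auto", seed=0)
        assert a.K == 3
        assert adjusted_rand_score(np.repeat([0, 1, 2], 20), a.labels) == 1.0

    def test_n_equals_k_degenerate(self, rng):
        X = rng.standard_normal((5, 2)) * 10
        a = spectral_cluster(X, K=5, seed=0)
        assert len(set(a.labels)) == 5

    def test_block_diagonal_recovers_components_any_seed(self):
        sizes = [5, 7, 6]
        n = sum(sizes)
        W = np.zeros((n, n))
        start = 0
        truth = []
        for k, s in enumerate(sizes):
            W[start : start + s, start : start + s] = 1 - np.eye(s)
            truth += [k] * s
            start += s
        for seed in (0, 1, 2):
            a = spectral_cluster(WeightMatrix(W, 1.0), K="auto", seed=seed)
            assert a.K == 3
            assert adjusted_rand_score(truth, a.labels) == 1.0


def _two_lines(n_per=100, noise=0.0, seed=0):
    """Points on two orthogonal lines with coefficients away from the origin."""
    rng = np.random.default_rng(seed)
    coef = rng.uniform(0.5, 2.0, size=(2, n_per)) * rng.choice([-1, 1], size=(2, n_per))
    b1 = np.array([1.0, 0.0, 0.0])
    b2 = np.array([0.0, 1.0, 0.0])
    pts = np.vstack([np.outer(coef[0], b1), np.outer(coef[1], b2)])
    pts += noise * rng.standard_normal(pts.shape)
    return pts, np.repeat([0, 1], n_per)


class TestSubspace:
    def test_orthogonal_lines_grouped_exactly(self):
        pts, truth = _two_lines()
        labels = pca_subspace_cluster(pts, k=2, n_sample=len(pts), dmax=3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_full_sample_covers_all_rows(self, rng):
        pts, _ = _two_lines(n_per=30)
        labels = pca_subspace_cluster(pts, k=2, n_sample=len(pts), dmax=3, seed=1)
        assert len(labels) == len(pts)
        assert set(labels) == {0, 1}

    def test_noise_robust_agreement(self):
        scores = []
        for seed in range(20):
            pts, truth = _two_lines(noise=0.01, seed=seed)
            # wider neighborhoods keep local PCA robust once noise rivals
            # the nearest-neighbor spacing
            labels = pca_subspace_cluster(pts, k=2, n_sample=len(pts), dmax=10, seed=seed)
            scores.append(adjusted_rand_score(truth, labels))
        assert np.mean(np.asarray(scores) >= 0.95) >= 0.95

    def test_unused_algorithm_parameters_warn(self):
        pts, _ = _two_lines(n_per=20)
        with pytest.warns(UserWarning, match="unused"):
            pca_subspace_cluster(pts, k=2, n_sample=len(pts), dmax=3, seed=0, t_max=1.0)

    def test_invalid_arguments(self):
        pts, _ = _two_lines(n_per=10)
        with pytest.raises(ValueError):
            pca_subspace_cluster(pts, k=30, n_sample=20, dmax=3)
        with pytest.raises(ValueError):
            pca_subspace_cluster(pts, k=2, n_sample=len(pts) + 1, dmax=3)


class TestRepresentatives:
    def test_identity_selection(self, rng):
        X = rng.standard_normal((10, 2))
        a = hierarchical_cluster(X, K=2)
        sel, idx = select_representatives(X, a, target_n=10)
        assert np.array_equal(idx, np.arange(10))
        assert np.array_equal(sel.X, X)

    def test_proportional_quotas_60_40(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (60, 2)), rng.normal((50, 0), 0.1, (40, 2))])
        labels = np.repeat([0, 1], [60, 40])
        a = ClusterAssignment.from_labels(labels, X)
        sel, idx = select_representatives(X, a, target_n=10)
        kept_labels = labels[idx]
        assert (kept_labels == 0).sum() == 6
        assert (kept_labels == 1).sum() == 4

    def test_kept_rows_are_closest_to_centroid(self, rng):
        X = rng.standard_normal((20, 3))
        labels = np.zeros(20, dtype=int)
        a = ClusterAssignment.from_labels(labels, X)
        _, idx = select_representatives(X, a, target_n=8)
        d = np.linalg.norm(X - X.mean(axis=0), axis=1)
        expected = np.sort(np.argsort(d, kind="stable")[:8])
        assert np.array_equal(idx, expected)

    def test_exact_output_size(self, rng):
        X = rng.standard_normal((57, 2))
        a = hierarchical_cluster(X, K=5)
        for target in (5, 13, 40, 57):
            sel, idx = select_representatives(X, a, target_n=target)
            assert sel.n_epochs == target

    def test_target_below_k_rejected(self, rng):
        X = rng.standard_normal((10, 2)) * 10
        a = hierarchical_cluster(X, K=4)
        with pytest.raises(ValueError):
            select_representatives(X, a, target_n=3)
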