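import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from tdpatterns.clustering import (
    KernelConfig,
    distance_to_kernel,
    dunn_index,
    kernel_kmeans,
    select_k,
    silhouette_index,
)
from tdpatterns.mdtw import pairwise_distance_matrix

from _oracles import brute_dunn, brute_silhouette


def block_distance(sizes, within, between, rng=None, noise=0.0):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    D = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        jitter = rng.uniform(0, noise, D.shape)
        D = D + (jitter + jitter.T) / 2
    np.fill_diagonal(D, 0.0)
    return D, labels + 1


class TestDistanceToKernel:
    def test_zero_distance_gives_all_ones(self):
        D = np.zeros((4, 4))
        K = distance_to_kernel(D, KernelConfig(sigma_rule="fixed", sigma_value=1.0))
        assert np.allclose(K, 1.0)

    def test_monotone_decreasing_in_distance(self):
        rng = np.random.default_rng(0)
        D, _ = block_distance([3, 3], 0.5, 4.0, rng, noise=0.2)
        K = distance_to_kernel(D, KernelConfig(sigma_rule="fixed", sigma_value=2.0))
        iu = np.triu_indices(6, k=1)
        order = np.argsort(D[iu])
        assert (np.diff(K[iu][order]) <= 1e-12).all()

    def test_two_block_structure_preserved(self):
        D, labels = block_distance([2, 2], 0.1, 10.0)
        K = distance_to_kernel(D)
        within = K[0, 1]
        between = K[0, 2]
        assert between < within

    def test_degenerate_zero_matrix_with_median_rule_errors(self):
        with pytest.raises(ValueError):
            distance_to_kernel(np.zeros((3, 3)))

    def test_psd_repair_leaves_unit_offdiagonal_structure(self):
        # an indefinite "kernel" made from a non-Euclidean distance
        rng = np.random.default_rng(1)
        D = rng.uniform(0.5, 3.0, (10, 10))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        K = distance_to_kernel(D, KernelConfig(sigma_rule="fixed", sigma_value=0.3))
        assert np.linalg.eigvalsh(K)[0] >= -1e-9


class TestKernelKMeans:
    def test_k_equal_one_and_n(self):
        D, _ = block_distance([3, 3], 0.5, 4.0)
        K = distance_to_kernel(D, KernelConfig(sigma_rule="fixed", sigma_value=1.0))
        res1 = kernel_kmeans(K, 1, seed=0)
        assert set(res1.labels) == {1}
        resn = kernel_kmeans(K, 6, seed=0)
        assert sorted(resn.labels) == [1, 2, 3, 4, 5, 6]
        assert resn.objective == pytest.approx(0.0, abs=1e-9)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kernel_kmeans(np.eye(3), 4)

    def test_planted_blocks_recovered_deterministically(self):
        rng = np.random.default_rng(2)
        D, truth = block_distance([20, 20], 0.5, 6.0, rng, noise=0.3)
        K = distance_to_kernel(D)
        res = kernel_kmeans(K, 2, seed=3)
        assert adjusted_rand_score(res.labels, truth) == 1.0
        res2 = kernel_kmeans(K, 2, seed=3)
        assert np.array_equal(res.labels, res2.labels)

    def test_objective_history_nonincreasing(self):
        rng = np.random.default_rng(4)
        D, _ = block_distance([15, 15, 15], 1.0, 5.0, rng, noise=0.5)
        K = distance_to_kernel(D)
        res = kernel_kmeans(K, 3, n_init=10, seed=5)
        for hist in res.all_histories:
            assert (np.diff(hist) <= 1e-9).all()


class TestValidityIndices:
    def test_two_clusters_perfect_separation(self):
        D, labels = block_distance([3, 3], 0.0, 1.0)
        assert silhouette_index(D, labels) == pytest.approx(1.0)

    def test_all_distances_equal_gives_zero_silhouette(self):
        D, labels = block_distance([3, 3], 1.0, 1.0)
        assert silhouette_index(D, labels) == pytest.approx(0.0)

    def test_single_cluster_rejected(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            silhouette_index(D, np.ones(3))
        with pytest.raises(ValueError):
            dunn_index(D, np.ones(3))

    def test_dunn_two_tight_blocks(self):
        D, labels = block_distance([3, 3], 1.0, 10.0)
        assert dunn_index(D, labels) == pytest.approx(10.0)

    def test_dunn_zero_diameter_rejected(self):
        D, labels = block_distance([2, 2], 0.0, 1.0)
        with pytest.raises(ValueError):
            dunn_index(D, labels)

    def test_merging_separated_clusters_decreases_dunn(self):
        rng = np.random.default_rng(6)
        D, labels = block_distance([4, 4, 4], 1.0, 8.0, rng, noise=0.2)
        merged = np.where(labels == 3, 2, labels)
        assert dunn_index(D, merged) < dunn_index(D, labels)

    def test_brute_force_agreement_small_instances(self):
        """Exact agreement with definition-level loops on all n<=8 instances."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            D = rng.uniform(0.1, 5.0, (n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            k = int(rng.integers(2, min(n, 4) + 1))
            labels = rng.integers(1, k + 1, n)
            if len(set(labels.tolist())) < 2:
                continue
            assert silhouette_index(D, labels) == pytest.approx(
                brute_silhouette(D, labels), abs=1e-12
            )
            if max(D[labels == c][:, labels == c].max() for c in set(labels)) > 0:
                assert dunn_index(D, labels) == pytest.approx(
                    brute_dunn(D, labels), abs=1e-12
                )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        D, labels = block_distance([4, 4, 4], 1.0, 5.0, rng, noise=0.3)
        permuted = np.take([0, 3, 1, 2], labels)
        assert silhouette_index(D, labels) == pytest.approx(
            silhouette_index(D, permuted)
        )
        assert dunn_index(D, labels) == pytest.approx(dunn_index(D, permuted))

    def test_agrees_with_sklearn_when_no_singletons(self):
        rng = np.random.default_rng(10)
        D, labels = block_distance([5, 5, 5], 1.0, 4.0, rng, noise=0.5)
        ours = silhouette_index(D, labels)
        theirs = silhouette_score(D, labels, metric="precomputed")
        assert ours == pytest.approx(theirs, abs=1e-12)


class TestSelectK:
    def test_duplicated_points_in_three_groups(self):
        D, labels = block_distance([3, 3, 3], 0.0, 2.0)
        tab = select_k(D, [3], KernelConfig(sigma_rule="fixed", sigma_value=1.0), seed=0)
        assert tab.loc[0, "silhouette"] == pytest.approx(1.0)

    def test_silhouette_peaks_at_four_archetypes(self, small_cohort):
        recalls, _, _ = small_cohort
        D = pairwise_distance_matrix(recalls)
        tab = select_k(D, range(3, 8), seed=1)
        best = tab.loc[tab["silhouette"].idxmax(), "k"]
        assert best == 4

    def test_out_of_range_k_rejected(self):
        D, _ = block_distance([3, 3], 1.0, 2.0)
        with pytest.raises(ValueError):
            select_k(D, [1])
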