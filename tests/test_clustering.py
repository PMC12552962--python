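"""Binary cut, hierarchical and combined clustering; difference score."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from gosum.clustering import (
    BinaryCutClustering,
    BinaryCutParams,
    ClusterAssignment,
    CombinedClustering,
    SimilarityAgglomerative,
    benchmark_methods,
    binary_cut,
    combined_cluster,
    difference_score,
    hierarchical_cluster,
)
from gosum.errors import InputError
from gosum.simulate import BlockSpec, synth_similarity

from oracles import pairwise_difference_score

ALL_METHODS = (binary_cut, hierarchical_cluster, combined_cluster)


def constant_matrix(n, off):
    v = np.full((n, n), off, dtype=float)
    np.fill_diagonal(v, 1.0)
    return v


def two_blocks(sizes=(4, 4), within=0.9, between=0.05):
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    v = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(v, 1.0)
    return v, labels


class TestBinaryCut:
    def test_constant_tight_matrix_is_one_cluster(self):
        est = BinaryCutClustering(cutoff=0.85).fit(constant_matrix(6, 0.9))
        assert est.n_clusters_ == 1

    def test_two_planted_blocks_recovered_exactly(self):
        v, labels = two_blocks()
        est = BinaryCutClustering(cutoff=0.85).fit(v)
        assert adjusted_rand_score(labels, est.labels_) == 1.0
        assert est.n_clusters_ == 2

    def test_cutoff_zero_is_single_cluster(self):
        v, _ = two_blocks()
        est = BinaryCutClustering(cutoff=0.0).fit(v)
        assert est.n_clusters_ == 1

    def test_kmeans_partitioner_recovers_blocks(self):
        v, labels = two_blocks(sizes=(6, 6))
        est = BinaryCutClustering(cutoff=0.85, partitioner="kmeans2",
                                  random_state=1).fit(v)
        assert adjusted_rand_score(labels, est.labels_) == 1.0

    def test_invalid_matrix_rejected(self):
        with pytest.raises(InputError):
            BinaryCutClustering().fit(np.array([[1.0, 0.2], [0.8, 1.0]]))
        with pytest.raises(InputError):
            BinaryCutClustering().fit(constant_matrix(4, 1.5))

    def test_bad_params_rejected(self):
        with pytest.raises(InputError):
            BinaryCutParams(cutoff=1.5)
        with pytest.raises(InputError):
            BinaryCutParams(min_split=1)
        with pytest.raises(InputError):
            BinaryCutParams(partitioner="spectral")

    def test_sklearn_protocol(self):
        est = BinaryCutClustering(cutoff=0.7)
        assert clone(est).get_params()["cutoff"] == 0.7
        v, _ = two_blocks()
        labels = est.fit_predict(v)
        assert labels.shape == (v.shape[0],)


class TestHierarchical:
    def test_silhouette_finds_two_blocks(self):
        v, labels = two_blocks(sizes=(5, 5))
        est = SimilarityAgglomerative().fit(v)
        assert est.n_clusters_ == 2
        assert adjusted_rand_score(labels, est.labels_) == 1.0

    def test_silhouette_choice_matches_brute_force(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform
        from sklearn.metrics import silhouette_score

        S, _ = synth_similarity(BlockSpec(block_sizes=[8, 9, 10], seed=3))
        est = SimilarityAgglomerative().fit(S.values)

        D = 1 - S.values
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="average")
        best_k, best_s = None, -np.inf
        for k in range(2, min(len(S) - 1, 25) + 1):
            flat = fcluster(Z, k, criterion="maxclust")
            if len(np.unique(flat)) < 2:
                continue
            s = silhouette_score(D, flat, metric="precomputed")
            if s > best_s + 1e-12:
                best_k, best_s, best_flat = k, s, flat
        assert adjusted_rand_score(best_flat, est.labels_) == 1.0
        assert est.n_clusters_ == len(np.unique(best_flat))

    def test_k_one_is_single_cluster(self):
        v, _ = two_blocks()
        est = SimilarityAgglomerative(n_clusters=1).fit(v)
        assert est.n_clusters_ == 1

    def test_k_equals_n_gives_singletons(self):
        v, _ = two_blocks()
        n = v.shape[0]
        est = SimilarityAgglomerative(n_clusters=n).fit(v)
        assert est.n_clusters_ == n

    def test_k_above_n_rejected(self):
        v, _ = two_blocks()
        with pytest.raises(InputError):
            SimilarityAgglomerative(n_clusters=9).fit(v)

    def test_complete_linkage_supported(self):
        v, labels = two_blocks(sizes=(5, 5))
        est = SimilarityAgglomerative(linkage="complete").fit(v)
        assert adjusted_rand_score(labels, est.labels_) == 1.0


class TestCombined:
    def test_identity_when_no_trigger_fires(self):
        S, _ = synth_similarity(BlockSpec(block_sizes=[10, 12, 9], seed=8))
        bin_est = BinaryCutClustering().fit(S.values)
        comb_est = CombinedClustering(refine_threshold=0.5,
                                      max_cluster_size=50).fit(S.values)
        assert comb_est.n_refined_ == 0
        assert np.array_equal(bin_est.labels_, comb_est.labels_)

    def test_loose_supercluster_split_into_planted_subblocks(self):
        # within 0.9, cross 0.3: whole-matrix score ~0.57, so binary cut
        # at cutoff 0.5 accepts it as one loose cluster; refinement at
        # threshold 0.6 must recover the two sub-blocks.
        v, labels = two_blocks(sizes=(6, 6), within=0.9, between=0.3)
        stage1 = BinaryCutClustering(cutoff=0.5).fit(v)
        assert stage1.n_clusters_ == 1
        comb = CombinedClustering(cutoff=0.5, refine_threshold=0.6).fit(v)
        assert comb.n_refined_ == 1
        assert adjusted_rand_score(labels, comb.labels_) == 1.0

    def test_two_items_below_threshold_become_singletons(self):
        v = constant_matrix(2, 0.3)
        comb = CombinedClustering(cutoff=0.2, refine_threshold=0.6).fit(v)
        assert comb.n_clusters_ == 2

    def test_oversize_trigger(self):
        v, _ = two_blocks(sizes=(6, 6), within=0.95, between=0.9)
        comb = CombinedClustering(cutoff=0.85, refine_threshold=0.1,
                                  max_cluster_size=5).fit(v)
        assert comb.n_refined_ >= 1


class TestPartitionAndOrderInvariance:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_every_term_labeled_once(self, method):
        S, _ = synth_similarity(BlockSpec(block_sizes=[9, 14, 8], seed=17))
        asg = method(S)
        assert set(asg.labels) == set(S.term_ids)
        assert set(asg.labels.values()) == set(range(1, asg.n_clusters + 1))

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_partition_invariant_under_permutation(self, method):
        S, _ = synth_similarity(BlockSpec(block_sizes=[8, 10, 12], seed=23))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(S.term_ids))
        S_perm = type(S)(term_ids=[S.term_ids[i] for i in perm],
                         values=S.values[np.ix_(perm, perm)])
        a = method(S)
        b = method(S_perm)
        la = [a.labels[t] for t in S.term_ids]
        lb = [b.labels[t] for t in S.term_ids]
        assert adjusted_rand_score(la, lb) == 1.0

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_planted_recovery_sample(self, method):
        hits = 0
        for seed in range(10):
            S, truth = synth_similarity(BlockSpec(
                block_sizes=[10, 15, 12], seed=seed))
            asg = method(S)
            if adjusted_rand_score(truth, asg.as_array(S.term_ids)) >= 0.9:
                hits += 1
        assert hits >= 9


class TestDifferenceScore:
    def test_constant_two_blocks_is_exactly_point_eight(self):
        v, labels = two_blocks(sizes=(4, 4), within=0.9, between=0.1)
        asg = ClusterAssignment(
            labels={f"item{i}": int(l) + 1 for i, l in enumerate(labels)},
            n_clusters=2, method="binary")
        assert difference_score(v, asg) == pytest.approx(0.8, abs=1e-15)

    def test_random_labels_on_constant_matrix_are_zero(self):
        v = constant_matrix(10, 0.4)
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 3, size=10)
        labels[:3] = [0, 1, 2]  # ensure >= 2 clusters
        assert difference_score(v, labels) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 1, size=(20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        labels = rng.integers(0, 4, size=20)
        labels[:2] = [0, 1]
        want = pairwise_difference_score(v.tolist(), labels.tolist())
        assert difference_score(v, labels) == pytest.approx(want, abs=1e-12)

    def test_single_cluster_rejected(self):
        v = constant_matrix(4, 0.5)
        with pytest.raises(InputError):
            difference_score(v, np.zeros(4, dtype=int))

    def test_all_singletons_within_mean_zero(self):
        v = constant_matrix(4, 0.5)
        d = difference_score(v, np.arange(4))
        assert d == pytest.approx(0.0 - 0.5)


class TestBenchmark:
    def test_shape_and_pairs(self):
        fixtures = [synth_similarity(BlockSpec(block_sizes=[8, 8],
                                               seed=s))[0] for s in (1, 2)]
        scores, stats = benchmark_methods(fixtures)
        assert scores.shape == (2, 3)
        assert set(scores.columns) == {"binary", "hclust", "combined"}
        assert len(stats) == 3  # all method pairs

    def test_identical_methods_flagged_degenerate(self):
        # tight fixtures: combined == binary, so that pair degenerates
        fixtures = [synth_similarity(BlockSpec(block_sizes=[8, 9],
                                               seed=s))[0] for s in (3, 4)]
        _, stats = benchmark_methods(fixtures)
        row = stats[(stats.method_a == "binary")
                    & (stats.method_b == "combined")].iloc[0]
        assert row.degenerate and row.p_value == 1.0

    def test_too_few_fixtures_rejected(self):
        with pytest.raises(InputError):
            benchmark_methods([constant_matrix(4, 0.9)])

    def test_bad_fixture_skipped(self):
        good = [synth_similarity(BlockSpec(block_sizes=[8, 8], seed=s))[0]
                for s in (5, 6)]
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        scores, _ = benchmark_methods([good[0], bad, good[1]])
        assert len(scores) == 2
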