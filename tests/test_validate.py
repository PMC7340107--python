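import itertools

import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

from spikecompat.cluster import AlgorithmSpec, Partition, get_spec
from spikecompat.features import FeatureSet
from spikecompat.validate import (
    CATEGORIES,
    GROUND_TRUTH,
    EvalConfig,
    accuracy,
    ball_hall,
    categorize,
    davies_bouldin,
    evaluate_all,
    index_consistency,
    inverted_rmse,
    jaccard_index,
    match_confusion_matrix,
    normalize_internal,
    optimal_confusion_matrix,
    rand_index,
    select_partition,
    trace_w,
)


def brute_force_pair_indices(gt, labels):
    """O(M^2) enumeration oracle for Rand and Jaccard."""
    tp = fp = fn = tn = 0
    for i, j in itertools.combinations(range(len(gt)), 2):
        same_g, same_c = gt[i] == gt[j], labels[i] == labels[j]
        tp += same_g and same_c
        fn += same_g and not same_c
        fp += same_c and not same_g
        tn += not same_g and not same_c
    total = tp + fp + fn + tn
    rand = (tp + tn) / total
    jac = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    return rand, jac


class TestConfusionMatrix:
    def test_perfect_partition_diagonal(self):
        gt = np.repeat([1, 2, 3], [10, 20, 30])
        cm = match_confusion_matrix(gt, Partition(labels=gt))
        np.testing.assert_array_equal(np.diag(cm.counts), [10, 20, 30])
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))
        assert cm.discarded == 0

    def test_hand_enumerated_example(self):
        gt = np.array([1, 1, 1, 2, 2, 3])
        labels = np.array([5, 5, 2, 2, 2, 9])
        cm = match_confusion_matrix(gt, labels)
        assert cm.mapping == {1: 5, 2: 2, 3: 9}
        np.testing.assert_array_equal(np.diag(cm.counts), [2, 2, 1])
        assert cm.counts[0, 1] == 1  # class-1 spike confused into class 2's cluster
        assert accuracy(cm, 6) == pytest.approx(100 * 5 / 6)
        # the greedy assignment here coincides with the exhaustive optimum
        opt = optimal_confusion_matrix(gt, labels)
        assert np.trace(opt.counts) == np.trace(cm.counts)

    def test_single_cluster_on_balanced_classes(self):
        gt = np.repeat([1, 2, 3], 1000)
        cm = match_confusion_matrix(gt, np.ones(3000, dtype=int))
        diag = np.diag(cm.counts)
        assert np.count_nonzero(diag) == 1
        assert diag.sum() == 1000

    def test_too_many_clusters_discarded(self):
        gt = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        labels = np.array([1, 1, 3, 3, 2, 2, 4, 4])  # 4 clusters, 2 classes
        cm = match_confusion_matrix(gt, labels)
        assert cm.discarded == 4
        np.testing.assert_array_equal(np.diag(cm.counts), [2, 2])
        assert cm.counts.sum() + cm.discarded == 8  # every spike audited

    def test_empty_partition_zero_matrix(self):
        gt = np.repeat([1, 2, 3], 5)
        cm = match_confusion_matrix(gt, Partition.empty_partition(15))
        assert cm.counts.sum() == 0
        assert accuracy(cm, 15) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            match_confusion_matrix(np.array([1, 2]), np.array([1, 2, 3]))

    def test_greedy_lower_bounds_optimal_assignment(self, rng):
        for _ in range(30):
            M = int(rng.integers(12, 60))
            gt = rng.integers(1, 5, size=M)
            labels = rng.integers(1, 6, size=M)
            greedy = np.trace(match_confusion_matrix(gt, labels).counts)
            optimal = np.trace(optimal_confusion_matrix(gt, labels).counts)
            assert greedy <= optimal


class TestExternalIndices:
    def test_identical_partitions_score_one(self):
        gt = np.repeat([1, 2, 3], 7)
        assert rand_index(gt, gt) == 1.0
        assert jaccard_index(gt, gt) == 1.0

    def test_hand_enumerated_pairs(self):
        gt = np.array([1, 1, 2, 2])
        labels = np.array([1, 2, 1, 2])
        assert rand_index(gt, labels) == pytest.approx(2 / 6)
        assert jaccard_index(gt, labels) == 0.0

    def test_single_cluster_rand_is_one_over_n(self):
        gt = np.repeat([1, 2, 3], 1000)
        assert rand_index(gt, np.ones(3000, dtype=int)) == pytest.approx(0.33, abs=0.005)

    def test_empty_partition_conventions(self):
        gt = np.repeat([1, 2], 5)
        assert rand_index(gt, Partition.empty_partition(10)) == 0.0
        with pytest.warns(UserWarning, match="no Jaccard"):
            assert jaccard_index(gt, Partition.empty_partition(10)) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            M = int(rng.integers(10, 120))
            gt = rng.integers(1, 5, size=M)
            labels = rng.integers(1, 7, size=M)
            r_oracle, j_oracle = brute_force_pair_indices(gt, labels)
            assert rand_index(gt, labels) == pytest.approx(r_oracle, abs=1e-12)
            assert jaccard_index(gt, labels) == pytest.approx(j_oracle, abs=1e-12)


def brute_force_internal(X, labels):
    """Double-loop oracle for BH / TrW / DB."""
    clusters = np.unique(labels)
    bh_terms, trw, deltas, centers = [], 0.0, [], []
    for c in clusters:
        pts = X[labels == c]
        center = pts.mean(axis=0)
        centers.append(center)
        sq = [(np.linalg.norm(p - center) ** 2) for p in pts]
        bh_terms.append(np.mean(sq))
        trw += np.sum(sq)
        deltas.append(np.mean([np.linalg.norm(p - center) for p in pts]))
    db_terms = []
    k = len(clusters)
    for i in range(k):
        db_terms.append(
            max(
                (deltas[i] + deltas[j]) / np.linalg.norm(np.asarray(centers[i]) - centers[j])
                for j in range(k)
                if j != i
            )
        )
    return np.mean(bh_terms), trw, np.mean(db_terms)


class TestInternalIndices:
    def test_hand_fixture(self, two_cluster_1d):
        X, part = two_cluster_1d
        assert ball_hall(X, part) == pytest.approx(2.5)
        assert trace_w(X, part) == pytest.approx(10.0)
        assert davies_bouldin(X, part) == pytest.approx(3 / 11)

    def test_singleton_clusters(self):
        X = np.array([[0.0, 0], [5, 5], [9, 1]])
        part = Partition(labels=np.array([1, 2, 3]))
        assert ball_hall(X, part) == 0.0
        assert trace_w(X, part) == 0.0
        assert davies_bouldin(X, part) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(50, 3))
            labels = rng.integers(1, 4, size=50)
            bh_o, trw_o, db_o = brute_force_internal(X, labels)
            assert ball_hall(X, labels) == pytest.approx(bh_o, abs=1e-9)
            assert trace_w(X, labels) == pytest.approx(trw_o, abs=1e-9)
            assert davies_bouldin(X, labels) == pytest.approx(db_o, abs=1e-9)

    def test_davies_bouldin_matches_sklearn(self, rng):
        X = rng.normal(size=(80, 3))
        labels = rng.integers(0, 3, size=80)
        assert davies_bouldin(X, labels) == pytest.approx(davies_bouldin_score(X, labels), abs=1e-9)

    def test_trace_w_equals_bh_relation_for_equal_clusters(self, rng):
        # for k equal-size clusters of n points each: TrW == k * n * BH-mean-per-cluster
        X = np.vstack([rng.normal(0, 1, (25, 2)), rng.normal(10, 1, (25, 2))])
        labels = np.repeat([1, 2], 25)
        assert trace_w(X, labels) == pytest.approx(2 * 25 * ball_hall(X, labels), rel=1e-9)

    def test_davies_bouldin_scale_invariance(self, rng):
        X = rng.normal(size=(60, 3))
        labels = rng.integers(1, 4, size=60)
        assert davies_bouldin(X * 37.5, labels) == pytest.approx(davies_bouldin(X, labels), abs=1e-9)

    def test_davies_bouldin_needs_two_clusters(self):
        with pytest.raises(ValueError, match="2 clusters"):
            davies_bouldin(np.zeros((5, 2)), np.ones(5, dtype=int))

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ball_hall(np.zeros((5, 2)), Partition.empty_partition(5))


class TestNormalization:
    def test_reference_scores_one(self):
        nii = normalize_internal({"gt": 0.8, "a": 0.3}, reference=0.8)
        assert nii["gt"] == 1.0

    def test_direct_substitution_example(self):
        nii = normalize_internal({"a": 0.2, "b": 0.5, "c": 1.0}, reference=1.0)
        assert nii == {"a": 0.0, "b": pytest.approx(0.375), "c": 1.0}

    def test_degenerate_range(self):
        nii = normalize_internal({"a": 0.7, "b": 0.7}, reference=0.7)
        assert nii == {"a": 1.0, "b": 1.0}
        nii2 = normalize_internal({"a": 0.7, "b": 0.7}, reference=0.9)
        assert nii2["a"] < 1.0  # reference extends the range set

    def test_reference_outside_observed_range_keeps_bounds(self):
        nii = normalize_internal({"a": 0.1, "b": 0.4}, reference=2.0)
        assert all(0.0 <= v <= 1.0 for v in nii.values())


class TestConsistency:
    def test_ideal_algorithm(self):
        rmse, inverted = inverted_rmse([1, 1, 1, 1, 1, 1])
        assert rmse == 0.0 and inverted == 1.0

    def test_direct_substitution(self):
        rmse, inverted = inverted_rmse([1, 1, 1, 1, 1, 0.4])
        assert rmse == pytest.approx(np.sqrt(0.06))
        assert inverted == pytest.approx(1 - np.sqrt(0.06))

    def test_worst_case(self):
        assert inverted_rmse([0, 0, 0, 0, 0, 0])[1] == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            inverted_rmse([1.5, 0.5])

    def test_index_consistency_examples(self):
        assert index_consistency([1, 1, 1]) == 0.0
        assert index_consistency([1, 0.5, 0]) == pytest.approx(np.var([1, 0.5, 0]))
        assert index_consistency([0.5, 1, 0]) == index_consistency([0, 0.5, 1])

    def test_index_consistency_flags_missing(self):
        with pytest.warns(UserWarning, match="missing"):
            assert np.isnan(index_consistency([1.0, float("nan"), 0.5]))


class TestCategorize:
    def test_ground_truth_is_ideal(self):
        cats = categorize({GROUND_TRUTH: 1.0, "a": 0.9, "b": 0.2})
        assert cats[GROUND_TRUTH] == "ideal"

    def test_quintile_binning_two_per_category(self):
        scores = {GROUND_TRUTH: 1.0}
        scores.update({f"alg{i}": 1.0 - i * 0.05 for i in range(10)})
        cats = categorize(scores)
        counts = {c: sum(v == c for v in cats.values()) for c in CATEGORIES[1:]}
        assert all(n == 2 for n in counts.values())

    def test_monotone_binning(self):
        scores = {f"alg{i}": 1.0 - i * 0.07 for i in range(12)}
        cats = categorize(scores)
        order = [CATEGORIES.index(cats[f"alg{i}"]) for i in range(12)]
        assert order == sorted(order)

    def test_fixed_thresholds(self):
        cats = categorize(
            {"a": 0.95, "b": 0.6, "c": 0.1},
            scheme="thresholds",
            thresholds=[0.9, 0.7, 0.5, 0.3, 0.2],
        )
        assert cats == {"a": "most-compatible", "b": "average", "c": "non-compatible"}


class TestSelectPartition:
    def test_minimum_rule(self):
        assert select_partition({1: 5, 2: 1, 3: 4, 4: 6}, "minimum") == 2

    def test_max_second_difference(self):
        assert select_partition({1: 10, 2: 6, 3: 5, 4: 4.8}, "max_second_difference") == 2

    def test_constant_series_tie_breaks_to_smallest(self):
        series = {2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0}
        for rule in ("minimum", "maximum", "max_second_difference", "min_second_difference"):
            assert select_partition(series, rule) == (2 if rule in ("minimum", "maximum") else 3)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            select_partition({1: 1.0, 2: 2.0}, "max_second_difference")


@pytest.fixture(scope="module")
def result(low_pool):
    from spikecompat.features import pca_features, wavelet_features

    feature_sets = [pca_features(low_pool, label="Epca"), wavelet_features(low_pool, label="Eks")]
    specs = [get_spec("kmeans").with_seed(5), get_spec("dbscan")]
    return evaluate_all(feature_sets, specs, EvalConfig(n_partitions=3))


class TestEvaluateAll:
    def test_ground_truth_row_is_ideal(self, result):
        scores = result.table.scores
        gt = scores[scores["algorithm"] == GROUND_TRUTH]
        assert np.allclose(gt[gt["criterion"] == "rand"]["raw"], 1.0)
        assert np.allclose(gt[gt["criterion"] == "accuracy"]["raw"], 100.0)
        nii = gt[gt["criterion"].isin(("DB", "BH", "TrW"))]["normalized"]
        assert np.allclose(nii, 1.0)

    def test_grid_shape(self, result):
        scores = result.table.scores
        # (ground-truth + 2 algorithms) x 2 feature-sets x 6 criteria
        assert len(scores) == 3 * 2 * 6
        assert len(result.table.consistency) == 3
        assert len(result.table.nii_variance) == 6

    def test_determinism(self, low_pool, result):
        from spikecompat.features import pca_features, wavelet_features

        feature_sets = [pca_features(low_pool, label="Epca"), wavelet_features(low_pool, label="Eks")]
        specs = [get_spec("kmeans").with_seed(5), get_spec("dbscan")]
        again = evaluate_all(feature_sets, specs, EvalConfig(n_partitions=3))
        import pandas as pd

        pd.testing.assert_frame_equal(again.table.scores, result.table.scores)
        pd.testing.assert_frame_equal(again.table.consistency, result.table.consistency)

    def test_label_permutation_invariance(self, low_pool):
        from spikecompat.features import pca_features

        fs = pca_features(low_pool, label="Epca")
        part = get_spec("kmeans").with_seed(5)
        from spikecompat.cluster import run_supervised

        p = run_supervised(part, fs, 3)
        relabel = {1: 3, 2: 1, 3: 2}
        permuted = Partition(labels=np.vectorize(relabel.get)(p.labels))
        gt = fs.gt_labels
        assert rand_index(gt, permuted) == rand_index(gt, p)
        assert jaccard_index(gt, permuted) == jaccard_index(gt, p)
        assert accuracy(match_confusion_matrix(gt, permuted), fs.M) == accuracy(
            match_confusion_matrix(gt, p), fs.M
        )
        assert ball_hall(fs, permuted) == pytest.approx(ball_hall(fs, p))
        assert davies_bouldin(fs, permuted) == pytest.approx(davies_bouldin(fs, p))

    def test_failures_degrade_not_abort(self, low_pool):
        from spikecompat.features import pca_features

        fs = pca_features(low_pool, label="Epca")
        # DBSCAN tuned to produce nothing: scores must still come out (as zeros)
        spec = AlgorithmSpec(name="dbscan", mode="unsupervised", params={"eps": 1e-9, "min_samples": 3})
        result = evaluate_all([fs], [spec], EvalConfig())
        row = result.table.scores
        got = row[(row["algorithm"] == "dbscan") & (row["criterion"] == "rand")]["raw"].iloc[0]
        assert got == 0.0
        assert result.partitions[("dbscan", "Epca")].empty
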