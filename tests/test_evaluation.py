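import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from string2go import (ConfusionCounts, auprc, centroid_distance_analysis,
                       confusion_metrics, evaluate_scores, f_tau, fmax,
                       holm_correction, lower_median, paired_tests)


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(0.6667, abs=1e-4)
        assert m["mcc"] == pytest.approx(0.4082, abs=1e-4)

    def test_perfect_prediction(self):
        m = confusion_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=5))
        assert m["f1"] == 1.0 and m["mcc"] == 1.0

    def test_zero_denominator_conventions(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, fn=3, tn=4))
        assert m == {"precision": 0.0, "recall": 0.0, "f1": 0.0, "mcc": 0.0}

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_metrics_bounded(self, counts):
        m = confusion_metrics(ConfusionCounts(*counts))
        assert 0 <= m["precision"] <= 1 and 0 <= m["recall"] <= 1
        assert 0 <= m["f1"] <= 1 and -1 <= m["mcc"] <= 1


class TestAUPRC:
    def test_worked_example(self):
        assert auprc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(0.8333,
                                                                  abs=1e-4)

    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.5, 0.4], [0, 0])

    def test_matches_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score
        for _ in range(100):
            n = int(rng.integers(2, 21))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                labels[0] = 1
            assert auprc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)

    def test_tied_scores_single_threshold(self):
        # all scores equal: one threshold, precision = base rate, recall 1
        assert auprc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == pytest.approx(0.5)


class TestFmax:
    def test_perfect_scores(self):
        truth = np.array([[1, 0], [1, 1]])
        res = fmax(truth.astype(float), truth)
        assert res["fmax"] == pytest.approx(1.0)
        assert res["tau_star"] == pytest.approx(1.0)

    def test_two_protein_toy(self):
        truth = np.array([[1, 0], [1, 1]])
        scores = np.array([[0.9, 0.2], [0.6, 0.4]])
        res = fmax(scores, truth)
        assert res["fmax"] == pytest.approx(1.0)
        assert res["tau_star"] == pytest.approx(0.40)

    def test_recall_non_increasing_in_tau(self, rng):
        scores = rng.random((10, 5))
        truth = (rng.random((10, 5)) < 0.4).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        curve = fmax(scores, truth)["curve"]
        assert (np.diff(curve.recall) <= 1e-12).all()
        assert (np.diff(curve.m) <= 0).all()

    def test_fmax_dominates_f_tau(self, rng):
        scores = rng.random((8, 4))
        truth = (rng.random((8, 4)) < 0.5).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        res = fmax(scores, truth)
        for tau in (0.1, 0.25, 0.5, 0.9):
            assert f_tau(scores, truth, tau) <= res["fmax"] + 1e-12

    def test_f_tau_at_tau_star_equals_fmax(self, rng):
        scores = rng.random((12, 6))
        truth = (rng.random((12, 6)) < 0.4).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        res = fmax(scores, truth)
        assert f_tau(scores, truth, res["tau_star"]) == res["fmax"]

    def test_protein_permutation_invariance(self, rng):
        scores = rng.random((9, 4))
        truth = (rng.random((9, 4)) < 0.5).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        perm = rng.permutation(9)
        assert fmax(scores, truth)["fmax"] == fmax(scores[perm],
                                                   truth[perm])["fmax"]

    def test_tau_one_with_low_scores_warns_zero(self):
        scores = np.array([[0.3, 0.2]])
        truth = np.array([[1, 0]])
        assert f_tau(scores, truth, 1.0) == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fmax(np.ones((1, 1)), np.ones((1, 1)), grid=[])

    def test_protein_without_truth_rejected(self):
        with pytest.raises(ValueError):
            fmax(np.ones((2, 2)), np.array([[1, 0], [0, 0]]))


class TestMedians:
    def test_lower_median_even_length(self):
        assert lower_median([0.1, 0.2, 0.3, 0.4]) == 0.2

    def test_odd_length(self):
        assert lower_median([3, 1, 2]) == 2

    def test_report_medians_within_range(self, rng):
        scores = rng.random((10, 5))
        truth = (rng.random((10, 5)) < 0.5).astype(int)
        truth[truth.sum(axis=1) == 0, 0] = 1
        rep = evaluate_scores("m", scores, truth, [f"t{i}" for i in range(5)])
        assert rep.f1.min() <= rep.median_f1 <= rep.f1.max()
        assert rep.mcc.min() <= rep.median_mcc <= rep.mcc.max()


class TestCentroidDistance:
    def test_identical_classes_zero_distance(self):
        X = np.tile([[0.0, 1.0]], (6, 1))
        labels = np.array([[1], [1], [1], [0], [0], [0]])
        res = centroid_distance_analysis(X, labels, [0.5])
        assert res["distances"][0] == pytest.approx(0.0)

    def test_unit_square_diagonal(self):
        X = np.array([[1.0, 1.0]] * 3 + [[0.0, 0.0]] * 3)
        labels = np.array([[1]] * 3 + [[0]] * 3)
        res = centroid_distance_analysis(X, labels, [0.9])
        assert res["distances"][0] == pytest.approx(np.sqrt(2))

    def test_correlation_with_distances_themselves(self, rng):
        X = rng.random((20, 3))
        labels = np.zeros((20, 3), dtype=int)
        labels[:10, 0] = 1
        labels[:5, 1] = 1
        labels[5:15, 2] = 1
        res = centroid_distance_analysis(X, labels, np.zeros(3))
        res2 = centroid_distance_analysis(X, labels, res["distances"])
        assert res2["correlation"] == pytest.approx(1.0)

    def test_constant_dimension_standardized_to_zero(self):
        X = np.array([[1.0, 5.0], [0.0, 5.0], [1.0, 5.0], [0.0, 5.0]])
        labels = np.array([[1], [0], [1], [0]])
        res = centroid_distance_analysis(X, labels, [0.1])
        assert res["distances"][0] == pytest.approx(1.0)  # only dim 0 counts


class TestPairedTests:
    def test_identical_vectors_no_rejection(self):
        a = np.array([0.1, 0.2, 0.3])
        res = paired_tests({"A": a, "B": a.copy()})
        assert res["p_value"] == 1.0 and not res["reject"]

    def test_constant_shift_exact_p(self):
        b = np.arange(10, dtype=float)
        res = paired_tests({"A": b + 1, "B": b})
        assert res["p_value"] == pytest.approx(2 * (1 / 2 ** 10))

    def test_holm_worked_example(self):
        reject, adjusted = holm_correction([0.01, 0.04], alpha=0.05)
        assert reject == [True, True]

    def test_three_methods_take_friedman_path(self, rng):
        base = rng.random(12)
        res = paired_tests({"A": base, "B": base + rng.random(12),
                            "C": base - rng.random(12)})
        assert res["test"] == "friedman"
        assert len(res["pairwise"]) == 3

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_tests({"A": np.ones(3), "B": np.ones(4)})
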