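import numpy as np
import pytest
from scipy.stats import spearmanr

from string2go import (AnnotationMatrix, NaiveFrequencyBaseline,
                       PPIHomologBaseline, TermSVMStack, TermVocabulary,
                       naive_baseline, ppi_homolog_baseline,
                       propagate_annotations)
from string2go.classifiers import positives_for_term
from string2go.splits import HomologyOracle

from conftest import make_dag, make_network
import pandas as pd


@pytest.fixture(scope="module")
def separable_toy():
    """Two well-separated point clouds: positives at +1^d, negatives at -1^d."""
    rng = np.random.default_rng(0)
    d = 4
    X = np.vstack([np.ones((20, d)) + 0.1 * rng.normal(size=(20, d)),
                   -np.ones((20, d)) + 0.1 * rng.normal(size=(20, d))])
    proteins = [f"p{i}" for i in range(40)]
    labels = pd.DataFrame({"t": [1] * 20 + [0] * 20}, index=proteins,
                          dtype="int8")
    return X, AnnotationMatrix(labels=labels)


@pytest.fixture(scope="module")
def fitted_stack(separable_toy):
    X, ann = separable_toy
    stack = TermSVMStack(c_grid=(1.0,), gamma_grid=(0.1, 1.0), folds=5,
                         seed=0)
    return stack.fit(X, ann)


class TestTermSVMs:
    def test_separable_cv_f1_perfect(self, fitted_stack):
        clf = fitted_stack.classifiers_["t"]
        assert clf.cv_f1 == pytest.approx(1.0)

    def test_posteriors_in_unit_interval(self, fitted_stack, separable_toy):
        X, _ = separable_toy
        scores = fitted_stack.predict_proba(X)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_true_positives_scored_above_half(self, fitted_stack,
                                              separable_toy):
        X, ann = separable_toy
        scores = fitted_stack.predict_proba(X)[:, 0]
        assert (scores[:20] > 0.5).all()
        assert (scores[20:] < 0.5).all()

    def test_calibration_preserves_ranking(self, fitted_stack,
                                           separable_toy):
        X, _ = separable_toy
        clf = fitted_stack.classifiers_["t"]
        rho = spearmanr(clf.decision_values(X), clf.posterior(X)).statistic
        assert rho == pytest.approx(1.0)

    def test_single_grid_point_selected(self, separable_toy):
        X, ann = separable_toy
        stack = TermSVMStack(c_grid=(4.0,), gamma_grid=(0.5,), folds=3,
                             seed=0).fit(X, ann)
        clf = stack.classifiers_["t"]
        assert (clf.C, clf.gamma) == (4.0, 0.5)

    def test_descendant_annotations_count_as_positive(self):
        dag = make_dag([("t_child", "t")])
        labels = pd.DataFrame(
            {"t": [0, 1], "t_child": [1, 0]},
            index=["p_desc_only", "p_direct"], dtype="int8")
        ann = AnnotationMatrix(labels=labels)
        pos = positives_for_term(ann, dag, "t")
        assert pos.tolist() == [True, True]

    def test_positive_set_contains_descendant_positive_sets(self):
        dag = make_dag([("t_child", "t")])
        rng = np.random.default_rng(1)
        labels = pd.DataFrame(
            {"t": rng.integers(0, 2, 30), "t_child": 0}, dtype="int8",
            index=[f"p{i}" for i in range(30)])
        labels.loc[labels["t"] == 1, "t_child"] = rng.integers(
            0, 2, int((labels["t"] == 1).sum())).astype("int8")
        ann = AnnotationMatrix(labels=labels)
        parent = positives_for_term(ann, dag, "t")
        child = positives_for_term(ann, dag, "t_child")
        assert (parent | ~child).all()  # child positives subset of parent's

    def test_term_without_positives_skipped(self, separable_toy):
        X, ann = separable_toy
        vocab = TermVocabulary(terms=["t", "t_absent"])
        stack = TermSVMStack(c_grid=(1.0,), gamma_grid=(0.5,), folds=3,
                             seed=0).fit(X, ann, vocab=vocab)
        scores = stack.predict_proba(X)
        assert (scores[:, 1] == 0).all()

    def test_dimension_mismatch(self, fitted_stack):
        with pytest.raises(ValueError, match="features"):
            fitted_stack.predict_proba(np.zeros((2, 9)))


class TestNaiveBaseline:
    @pytest.fixture(scope="class")
    def train_ann(self):
        labels = pd.DataFrame({"t": [1] * 4 + [0] * 6, "u": [0] * 10},
                              index=[f"p{i}" for i in range(10)],
                              dtype="int8")
        return AnnotationMatrix(labels=labels)

    def test_frequency_score(self, train_ann):
        vocab = TermVocabulary(terms=["t"])
        scores = naive_baseline(train_ann, vocab, ["q1", "q2", "q3"])
        np.testing.assert_allclose(scores, 0.4)

    def test_unseen_term_scores_zero(self, train_ann):
        vocab = TermVocabulary(terms=["t", "missing"])
        scores = naive_baseline(train_ann, vocab, ["q1"])
        assert scores[0, 1] == 0.0

    def test_rows_identical_zero_variance(self, train_ann):
        vocab = TermVocabulary(terms=["t", "u"])
        scores = naive_baseline(train_ann, vocab, [f"q{i}" for i in range(5)])
        assert np.ptp(scores, axis=0).max() == 0.0

    def test_empty_training_rejected(self):
        empty = AnnotationMatrix(labels=pd.DataFrame(dtype="int8"))
        with pytest.raises(ValueError):
            NaiveFrequencyBaseline().fit(empty)


class TestPPIHomologBaseline:
    @pytest.fixture(scope="class")
    def setting(self):
        net = make_network([("p", "x", 0.9), ("p2", "x", 0.9)])
        labels = pd.DataFrame({"t": [1, 0], "u": [1, 1]},
                              index=["h1", "h2"], dtype="int8")
        ann = AnnotationMatrix(labels=labels)
        vocab = TermVocabulary(terms=["t", "u"])
        return net, ann, vocab

    def test_single_homolog_full_transfer(self, setting):
        net, ann, vocab = setting
        oracle = HomologyOracle({("x", "h1"): 1e-8})
        scores = ppi_homolog_baseline(net, ann, oracle, vocab, ["p"])
        assert scores[0].tolist() == [1.0, 1.0]

    def test_fractional_votes(self, setting):
        net, ann, vocab = setting
        oracle = HomologyOracle({("x", "h1"): 1e-8, ("x", "h2"): 1e-8})
        scores = ppi_homolog_baseline(net, ann, oracle, vocab, ["p"])
        assert scores[0].tolist() == [0.5, 1.0]

    def test_protein_absent_from_network(self, setting):
        net, ann, vocab = setting
        oracle = HomologyOracle({("x", "h1"): 1e-8})
        scores = ppi_homolog_baseline(net, ann, oracle, vocab, ["ghost"])
        assert (scores == 0).all()

    def test_evalue_threshold_respected(self, setting):
        net, ann, vocab = setting
        oracle = HomologyOracle({("x", "h1"): 1e-1})
        scores = ppi_homolog_baseline(net, ann, oracle, vocab, ["p"],
                                      evalue_threshold=1e-2)
        assert (scores == 0).all()
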