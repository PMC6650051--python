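"""Per-term calibrated SVMs and the Naive / PPI-homolog baselines.

The third pipeline stage trains one RBF-kernel SVM per vocabulary term.
Positives for a term t are the training proteins annotated with t *or any
is_a descendant of t*; everything else is negative.  (C, gamma) are chosen
by grid search maximizing mean F1 under stratified k-fold cross-validation,
and a Platt-style sigmoid fitted on out-of-fold decision values maps raw
margins to posterior probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import binary_confusion, confusion_metrics
from .network import WeightedNetwork
from .ontology import AnnotationMatrix, OntologyDAG, TermVocabulary

logger = logging.getLogger(__name__)

#: Default log-spaced hyperparameter grid for the RBF SVM.
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 11, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-11, 5, 2))


@dataclass
class TermClassifier:
    """A trained per-term SVM with a monotone probability calibration."""

    term: str
    svm: SVC
    platt: LogisticRegression
    C: float
    gamma: float
    cv_f1: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(X)

    def posterior(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X).reshape(-1, 1)
        return self.platt.predict_proba(d)[:, 1]


def positives_for_term(ann: AnnotationMatrix, dag: OntologyDAG,
                       term: str) -> np.ndarray:
    """Boolean mask over ann.proteins: annotated with term or a descendant."""
    terms = set(ann.terms)
    relevant = ({term} | (dag.descendants(term) if term in dag else set()))
    cols = [t for t in relevant if t in terms]
    if not cols:
        return np.zeros(len(ann.proteins), dtype=bool)
    return (ann.labels[cols].to_numpy().sum(axis=1) > 0)


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> LogisticRegression:
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lr.fit(decision.reshape(-1, 1), y)
    return lr


def _grid_search_term(X: np.ndarray, y: np.ndarray, c_grid, gamma_grid,
                      folds: int, seed: int):
    """Mean CV F1 per (C, gamma); ties break to smaller C, then gamma."""
    n_pos = int(y.sum())
    n_splits = min(folds, n_pos, int((1 - y).sum()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            f1s = []
            for tr, va in splits:
                svm = SVC(kernel="rbf", C=C, gamma=gamma)
                svm.fit(X[tr], y[tr])
                pred = svm.predict(X[va])
                f1s.append(confusion_metrics(
                    binary_confusion(y[va], pred))["f1"])
            mean_f1 = float(np.mean(f1s))
            if best is None or mean_f1 > best[0] + 1e-12:
                best = (mean_f1, C, gamma)
    mean_f1, C, gamma = best
    # out-of-fold decision values at the selected point, for calibration
    decision = np.zeros(len(y))
    for tr, va in splits:
        svm = SVC(kernel="rbf", C=C, gamma=gamma)
        svm.fit(X[tr], y[tr])
        decision[va] = svm.decision_function(X[va])
    return C, gamma, mean_f1, decision, n_splits


class TermSVMStack(BaseEstimator):
    """One calibrated RBF SVM per vocabulary term, sklearn-style.

    ``fit`` takes the representation matrix and the (propagated) annotation
    matrix restricted to the training proteins; ``predict_proba`` returns
    the protein x term posterior score matrix in [0, 1].  Terms without
    positives are skipped (scored 0) with a warning; terms with fewer
    positives than ``folds`` fall back to fewer folds (min 2).
    """

    def __init__(self, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 folds: int = 10, seed: int = 0):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.folds = folds
        self.seed = seed

    def fit(self, X, ann: AnnotationMatrix, vocab: TermVocabulary | None = None,
            dag: OntologyDAG | None = None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] != len(ann.proteins):
            raise ValueError("X rows must cover all annotated proteins")
        terms = list(vocab) if vocab is not None else list(ann.terms)
        self.terms_ = terms
        self.input_dim_ = X.shape[1]
        self.classifiers_ = {}
        for term in terms:
            if dag is not None:
                y = positives_for_term(ann, dag, term).astype(int)
            elif term in ann.labels.columns:
                y = (ann.labels[term].to_numpy() > 0).astype(int)
            else:
                y = np.zeros(X.shape[0], dtype=int)
            n_pos = int(y.sum())
            if n_pos == 0 or n_pos == len(y):
                logger.warning("term %s skipped (%d positives of %d)",
                               term, n_pos, len(y))
                continue
            if n_pos < self.folds:
                logger.warning("term %s has %d < %d positives; reducing folds",
                               term, n_pos, self.folds)
            C, gamma, cv_f1, decision, _ = _grid_search_term(
                X, y, self.c_grid, self.gamma_grid, self.folds, self.seed)
            svm = SVC(kernel="rbf", C=C, gamma=gamma)
            svm.fit(X, y)
            platt = _fit_platt(decision, y)
            self.classifiers_[term] = TermClassifier(
                term=term, svm=svm, platt=platt, C=C, gamma=gamma,
                cv_f1=cv_f1)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim_:
            raise ValueError(
                f"input has {X.shape[1]} features, stack expects "
                f"{self.input_dim_}")
        scores = np.zeros((X.shape[0], len(self.terms_)))
        for j, term in enumerate(self.terms_):
            clf = self.classifiers_.get(term)
            if clf is not None:
                scores[:, j] = clf.posterior(X)
        return scores


def train_term_svms(X, ann: AnnotationMatrix, vocab: TermVocabulary,
                    dag: OntologyDAG, c_grid=DEFAULT_C_GRID,
                    gamma_grid=DEFAULT_GAMMA_GRID, folds: int = 10,
                    seed: int = 0) -> TermSVMStack:
    stack = TermSVMStack(c_grid=c_grid, gamma_grid=gamma_grid, folds=folds,
                         seed=seed)
    return stack.fit(X, ann, vocab=vocab, dag=dag)


def predict_posteriors(stack: TermSVMStack, X) -> np.ndarray:
    return stack.predict_proba(X)


# ---------------------------------------------------------------------------
# baselines


class NaiveFrequencyBaseline(BaseEstimator):
    """Scores every protein with each term's training annotation frequency."""

    def fit(self, train_ann: AnnotationMatrix,
            vocab: TermVocabulary | None = None):
        if not train_ann.proteins:
            raise ValueError("training annotation matrix is empty")
        terms = list(vocab) if vocab is not None else list(train_ann.terms)
        n = len(train_ann.proteins)
        freq = []
        for t in terms:
            if t in train_ann.labels.columns:
                freq.append(float(train_ann.labels[t].sum()) / n)
            else:
                freq.append(0.0)
        self.terms_ = terms
        self.frequencies_ = np.array(freq)
        return self

    def predict_proba(self, protein_ids) -> np.ndarray:
        return np.tile(self.frequencies_, (len(list(protein_ids)), 1))


def naive_baseline(train_ann: AnnotationMatrix, vocab: TermVocabulary,
                   test_proteins) -> np.ndarray:
    return NaiveFrequencyBaseline().fit(train_ann, vocab).predict_proba(
        test_proteins)


class PPIHomologBaseline(BaseEstimator):
    """Annotation transfer through PPI partners' homologs.

    For a target protein p, gather H(p): annotated training proteins
    homologous (E-value <= threshold) to any PPI partner of p.  The score
    for term t is the fraction of H(p) annotated with t; 0 when H(p) is
    empty or p is missing from the network.
    """

    def __init__(self, evalue_threshold: float = 1e-2):
        self.evalue_threshold = evalue_threshold

    def fit(self, net: WeightedNetwork, train_ann: AnnotationMatrix,
            homology, vocab: TermVocabulary | None = None):
        self.net_ = net
        self.train_ann_ = train_ann
        self.homology_ = homology
        self.terms_ = list(vocab) if vocab is not None else list(
            train_ann.terms)
        return self

    def predict_proba(self, protein_ids) -> np.ndarray:
        g = self.net_.graph
        ann = self.train_ann_
        train_set = list(ann.proteins)
        labels = ann.labels
        scores = np.zeros((len(list(protein_ids)), len(self.terms_)))
        cols = [t for t in self.terms_ if t in labels.columns]
        col_idx = {t: j for j, t in enumerate(self.terms_)}
        for i, p in enumerate(protein_ids):
            if p not in g:
                logger.debug("protein %s absent from the network", p)
                continue
            homologs: set[str] = set()
            for partner in g.neighbors(p):
                for h in train_set:
                    e = self.homology_.evalue(partner, h)
                    if e is not None and e <= self.evalue_threshold:
                        homologs.add(h)
            if not homologs:
                continue
            sub = labels.loc[sorted(homologs), cols]
            frac = sub.to_numpy().mean(axis=0)
            for t, v in zip(cols, frac):
                scores[i, col_idx[t]] = v
        return scores


def ppi_homolog_baseline(net: WeightedNetwork, train_ann: AnnotationMatrix,
                         homology, vocab: TermVocabulary, test_proteins,
                         evalue_threshold: float = 1e-2) -> np.ndarray:
    model = PPIHomologBaseline(evalue_threshold=evalue_threshold)
    model.fit(net, train_ann, homology, vocab=vocab)
    return model.predict_proba(test_proteins)
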