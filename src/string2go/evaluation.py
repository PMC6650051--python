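"""Term-centric and protein-centric evaluation metrics.

Term-centric: per-term precision, recall, F1, Matthews correlation
coefficient (MCC) and area under the precision-recall curve (AUPRC),
summarized across the vocabulary by medians.  Protein-centric: the
CAFA-style Fmax protocol — sweep a decision threshold tau over a grid,
average per-protein precision over the proteins with at least one
prediction above tau (m_tau of them) and per-protein recall over all n
proteins, and take the maximum harmonic mean; F_tau re-evaluates the same
averaged F at a threshold carried over from another evaluation set.

Zero-denominator conventions: precision/recall/F1/MCC are 0 when their
denominator vanishes; AUPRC is undefined (NaN) without positives and such
terms are excluded from medians with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_TAU_GRID = np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, F1 (harmonic mean) and MCC from binary counts.

    Any zero denominator makes the corresponding metric 0.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    denom = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return {"precision": precision, "recall": recall, "f1": f1, "mcc": mcc}


def binary_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
    )


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve over all score thresholds.

    Step interpolation: sum over the descending-score sweep of
    (R_i - R_{i-1}) * P_i; tied scores form a single threshold.  Raises if
    there is no positive label.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    area = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # tie block = one threshold
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


@dataclass
class ThresholdCurve:
    taus: np.ndarray
    precision: np.ndarray  # averaged over m_tau proteins
    recall: np.ndarray     # averaged over all n proteins
    f: np.ndarray
    m: np.ndarray          # proteins with >=1 prediction >= tau
    n: int


def _averaged_pr(scores: np.ndarray, truth: np.ndarray, tau: float):
    """Averaged precision/recall of the tau-thresholded prediction sets."""
    pred = scores >= tau
    tp = (pred & (truth > 0)).sum(axis=1)
    npred = pred.sum(axis=1)
    ntrue = (truth > 0).sum(axis=1)
    has_pred = npred > 0
    m = int(has_pred.sum())
    n = scores.shape[0]
    if m:
        prec = float(np.mean(tp[has_pred] / npred[has_pred]))
    else:
        prec = 0.0
    rec = float(np.sum(tp / np.maximum(ntrue, 1)) / n)
    return prec, rec, m


def fmax(scores: np.ndarray, truth: np.ndarray,
         grid=DEFAULT_TAU_GRID) -> dict:
    """Protein-centric Fmax over a threshold grid.

    Returns the maximum averaged F, the largest tau attaining it (the most
    conservative maximizing threshold), and the full :class:`ThresholdCurve`.
    Thresholds leaving every protein without predictions are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must be aligned")
    if (truth.sum(axis=1) == 0).any():
        raise ValueError("every evaluated protein needs >= 1 true term")
    precs, recs, fs, ms = [], [], [], []
    for tau in grid:
        prec, rec, m = _averaged_pr(scores, truth, tau)
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        fs.append(f)
        ms.append(m)
    curve = ThresholdCurve(
        taus=grid, precision=np.array(precs), recall=np.array(recs),
        f=np.array(fs), m=np.array(ms), n=scores.shape[0])
    usable = curve.m > 0
    if not usable.any():
        return {"fmax": 0.0, "tau_star": float(grid[0]), "curve": curve}
    f_usable = np.where(usable, curve.f, -np.inf)
    best = f_usable.max()
    tau_star = grid[np.flatnonzero(f_usable == best).max()]
    return {"fmax": float(best), "tau_star": float(tau_star), "curve": curve}


def f_tau(scores: np.ndarray, truth: np.ndarray, tau: float) -> float:
    """Averaged F at a fixed threshold (no maximization)."""
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    prec, rec, m = _averaged_pr(scores, truth, tau)
    if m == 0:
        logger.warning("no protein has a prediction >= tau=%g; F_tau = 0", tau)
        return 0.0
    return 2 * prec * rec / (prec + rec) if prec + rec else 0.0


def lower_median(values) -> float:
    """50th percentile, taking the lower of the two middle values when even."""
    vals = sorted(values)
    if not vals:
        raise ValueError("median of empty sequence")
    return vals[(len(vals) - 1) // 2]


@dataclass
class EvaluationReport:
    """Per-term metrics plus protein-centric summary for one method."""

    method: str
    terms: list[str]
    f1: np.ndarray
    mcc: np.ndarray
    auprc: np.ndarray  # NaN where undefined
    fmax: float = float("nan")
    tau_star: float = float("nan")
    f_tau: float = float("nan")
    extras: dict = field(default_factory=dict)

    @property
    def median_f1(self) -> float:
        return lower_median(self.f1)

    @property
    def median_mcc(self) -> float:
        return lower_median(self.mcc)

    @property
    def median_auprc(self) -> float:
        vals = self.auprc[~np.isnan(self.auprc)]
        if vals.size < self.auprc.size:
            logger.warning("excluding %d terms with undefined AUPRC from the "
                           "median", self.auprc.size - vals.size)
        return lower_median(vals) if vals.size else float("nan")

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"term": self.terms, "f1": self.f1,
                             "mcc": self.mcc, "auprc": self.auprc})


def evaluate_scores(method: str, scores: np.ndarray, truth: np.ndarray,
                    terms: list[str], threshold: float = 0.5,
                    grid=DEFAULT_TAU_GRID,
                    protein_centric: bool = True) -> EvaluationReport:
    """Full term-centric (threshold 0.5) + protein-centric report."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    f1s, mccs, auprcs = [], [], []
    for j in range(truth.shape[1]):
        c = binary_confusion(truth[:, j], scores[:, j] >= threshold)
        m = confusion_metrics(c)
        f1s.append(m["f1"])
        mccs.append(m["mcc"])
        if truth[:, j].sum() > 0:
            auprcs.append(auprc(scores[:, j], truth[:, j]))
        else:
            auprcs.append(float("nan"))
    report = EvaluationReport(method=method, terms=list(terms),
                              f1=np.array(f1s), mcc=np.array(mccs),
                              auprc=np.array(auprcs))
    if protein_centric:
        keep = truth.sum(axis=1) > 0
        if keep.any():
            res = fmax(scores[keep], truth[keep], grid=grid)
            report.fmax = res["fmax"]
            report.tau_star = res["tau_star"]
            report.f_tau = f_tau(scores[keep], truth[keep], res["tau_star"])
    return report


def centroid_distance_analysis(X: np.ndarray, labels_per_term: np.ndarray,
                               f1_per_term) -> dict:
    """Class-separation analysis of a representation.

    Each representation dimension is min-max standardized to [0, 1] over
    the analyzed proteins (constant dimensions become 0, with a warning);
    per term, the Euclidean distance between the annotated and
    not-annotated class centroids is computed, and the Pearson correlation
    between those distances and the per-term F1 scores is reported.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels_per_term)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning("%d constant dimensions standardized to 0",
                       int(constant.sum()))
    span[constant] = 1.0
    Z = (X - lo) / span
    Z[:, constant] = 0.0
    distances = []
    for j in range(labels.shape[1]):
        pos = labels[:, j] > 0
        if not pos.any() or pos.all():
            raise ValueError(f"term column {j} has an empty class")
        d = np.linalg.norm(Z[pos].mean(axis=0) - Z[~pos].mean(axis=0))
        distances.append(float(d))
    distances = np.array(distances)
    f1 = np.asarray(f1_per_term, dtype=float)
    if np.std(distances) == 0 or np.std(f1) == 0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(distances, f1)[0])
    return {"distances": distances, "correlation": corr}


def paired_tests(per_term_scores: dict[str, np.ndarray],
                 alpha: float = 0.05) -> dict:
    """Compare methods by per-term score vectors.

    Two methods: two-tailed Wilcoxon signed-rank (zero differences
    dropped; exact null for n <= 25, normal approximation otherwise).
    More than two: Friedman test, then Holm-corrected pairwise Wilcoxon.
    """
    names = list(per_term_scores)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    vectors = [np.asarray(per_term_scores[k], dtype=float) for k in names]
    length = {len(v) for v in vectors}
    if len(length) != 1:
        raise ValueError("per-term vectors must share the same term list")

    def wilcoxon_pair(a, b):
        diff = a - b
        nz = diff != 0
        if not nz.any():
            return 1.0
        n = int(nz.sum())
        method = "exact" if n <= 25 else "approx"
        return float(stats.wilcoxon(a[nz], b[nz], zero_method="wilcox",
                                    alternative="two-sided",
                                    method=method).pvalue)

    out: dict = {"methods": names, "alpha": alpha}
    if len(names) == 2:
        p = wilcoxon_pair(vectors[0], vectors[1])
        out["test"] = "wilcoxon"
        out["p_value"] = p
        out["reject"] = p < alpha
        return out
    if all(np.allclose(v, vectors[0]) for v in vectors[1:]):
        out["test"] = "friedman"
        out["p_value"] = 1.0
        out["pairwise"] = []
        return out
    stat, p = stats.friedmanchisquare(*vectors)
    out["test"] = "friedman"
    out["statistic"] = float(stat)
    out["p_value"] = float(p)
    pairs, raw = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append((names[i], names[j]))
            raw.append(wilcoxon_pair(vectors[i], vectors[j]))
    reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    out["pairwise"] = [
        {"pair": pair, "p_raw": float(pr), "p_holm": float(pa),
         "reject": bool(rj)}
        for pair, pr, pa, rj in zip(pairs, raw, adjusted, reject)
    ]
    return out


def holm_correction(p_values, alpha: float = 0.05):
    """Holm step-down: returns (reject flags, adjusted p-values)."""
    reject, adjusted, _, _ = multipletests(list(p_values), alpha=alpha,
                                           method="holm")
    return list(map(bool, reject)), list(map(float, adjusted))
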