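"""Evaluation battery: group statistics, confusion matrices,
one-vs-rest ROC / precision-recall, Youden operating points, F1 and
percentile-bootstrap confidence intervals.

ROC and PR curves come from scikit-learn; with ties contributing ½,
the trapezoidal ROC AUC equals the Mann-Whitney pairwise statistic
(tests verify this against brute-force pair counting). PR-AUC uses the
average-precision (step) convention rather than trapezoidal
interpolation, which would be optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

__all__ = [
    "ConfusionMatrix",
    "CurveSet",
    "BootstrapCI",
    "EvalReport",
    "confusion",
    "binary_auc",
    "roc_ovr",
    "youden_point",
    "pr_ovr",
    "bootstrap_ci",
    "mann_whitney",
    "group_stats",
    "evaluate_multiclass",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[int, ...]

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def true_positive_rates(self) -> np.ndarray:
        row = self.counts.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    @property
    def normalized(self) -> np.ndarray:
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, self.counts / row, np.nan)


@dataclass(frozen=True)
class CurveSet:
    """One class's ROC and PR curves with their summary areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    auc: float
    precision: np.ndarray
    recall: np.ndarray
    pr_thresholds: np.ndarray
    pr_auc: float
    f1: float


@dataclass(frozen=True)
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    n_reps: int
    n_degenerate: int = 0


@dataclass(frozen=True)
class EvalReport:
    """Everything the multi-class evaluation produces."""

    confusion: ConfusionMatrix
    curves: dict[int, CurveSet]
    auc_cis: dict[int, BootstrapCI] = field(default_factory=dict)
    youden: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.confusion.accuracy,
            "true_positive_rates": {
                int(c): float(t) for c, t in
                zip(self.confusion.classes, self.confusion.true_positive_rates)
            },
            "confusion_counts": self.confusion.counts.tolist(),
            "per_class": {
                int(c): {
                    "auc": cs.auc,
                    "pr_auc": cs.pr_auc,
                    "f1": cs.f1,
                    **({"auc_ci": [self.auc_cis[c].lower, self.auc_cis[c].upper]}
                       if c in self.auc_cis else {}),
                    **({"sensitivity": self.youden[c]["sensitivity"],
                        "specificity": self.youden[c]["specificity"]}
                       if c in self.youden else {}),
                }
                for c, cs in self.curves.items()
            },
        }


def confusion(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    classes: tuple[int, ...] | None = None,
) -> ConfusionMatrix:
    """Confusion matrix with overall accuracy and per-class TPRs."""
    t = np.asarray(true_labels).ravel()
    p = np.asarray(predicted_labels).ravel()
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != p.shape:
        raise ValueError("label arrays differ in length")
    if classes is None:
        classes = tuple(int(c) for c in np.unique(np.concatenate([t, p])))
    counts = skm.confusion_matrix(t, p, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=classes)


def binary_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal ROC AUC (ties ½); equals the normalized
    Mann-Whitney pair statistic."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores).ravel()
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: only one class present")
    return float(skm.roc_auc_score(labels, scores))


def _binarize(true_labels: np.ndarray, positive_class: int) -> np.ndarray:
    return (np.asarray(true_labels).ravel() == positive_class).astype(int)


def roc_ovr(
    scores: np.ndarray,
    true_labels: np.ndarray,
    positive_class: int,
    class_order: tuple[int, ...] | None = None,
) -> CurveSet:
    """One-vs-rest ROC (and PR) for one class.

    ``scores`` is either a 1-D score vector for the positive class or
    an (n, k) probability matrix with ``class_order`` naming columns.
    """
    s = _class_scores(scores, positive_class, class_order)
    y = _binarize(true_labels, positive_class)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need at least one positive and one negative instance")
    fpr, tpr, thr = skm.roc_curve(y, s)
    prec, rec, pr_thr = skm.precision_recall_curve(y, s)
    return CurveSet(
        fpr=fpr, tpr=tpr, roc_thresholds=thr,
        auc=float(skm.auc(fpr, tpr)),
        precision=prec, recall=rec, pr_thresholds=pr_thr,
        pr_auc=float(skm.average_precision_score(y, s)),
        f1=np.nan,
    )


def _class_scores(scores, positive_class, class_order) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        return scores
    if class_order is None:
        raise ValueError("matrix scores require class_order")
    return scores[:, list(class_order).index(positive_class)]


def youden_point(curves: CurveSet) -> dict[str, float]:
    """Operating point maximizing J = sensitivity + specificity − 1.

    Ties broken toward higher specificity, then higher threshold.
    """
    j = curves.tpr - curves.fpr
    spec = 1.0 - curves.fpr
    order = np.lexsort((curves.roc_thresholds, spec, j))
    best = order[-1]
    return {
        "threshold": float(curves.roc_thresholds[best]),
        "sensitivity": float(curves.tpr[best]),
        "specificity": float(spec[best]),
        "j": float(j[best]),
    }


def pr_ovr(
    scores: np.ndarray,
    true_labels: np.ndarray,
    positive_class: int,
    predicted_labels: np.ndarray | None = None,
    class_order: tuple[int, ...] | None = None,
) -> CurveSet:
    """Precision-recall curve, average precision, and F1 at the hard
    labels (when provided)."""
    s = _class_scores(scores, positive_class, class_order)
    y = _binarize(true_labels, positive_class)
    if y.sum() == 0:
        raise ValueError("recall undefined without positive instances")
    prec, rec, pr_thr = skm.precision_recall_curve(y, s)
    ap = float(skm.average_precision_score(y, s))
    f1 = np.nan
    if predicted_labels is not None:
        yp = _binarize(predicted_labels, positive_class)
        f1 = float(skm.f1_score(y, yp, zero_division=0.0))
    roc_part = (np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.array([np.inf, -np.inf]))
    try:
        fpr, tpr, thr = skm.roc_curve(y, s)
        auc = float(skm.auc(fpr, tpr))
    except ValueError:
        (fpr, tpr, thr), auc = roc_part, np.nan
    return CurveSet(fpr=fpr, tpr=tpr, roc_thresholds=thr, auc=auc,
                    precision=prec, recall=rec, pr_thresholds=pr_thr,
                    pr_auc=ap, f1=f1)


def _vectorized_auc(y: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rank-based AUC per row of (reps, n) resample matrices."""
    ranks = stats.rankdata(s, axis=1)
    n_pos = y.sum(axis=1)
    n_neg = y.shape[1] - n_pos
    r_pos = (ranks * y).sum(axis=1)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return u / (n_pos * n_neg)


def bootstrap_ci(
    metric_fn,
    labels: np.ndarray,
    scores: np.ndarray,
    n_reps: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile-bootstrap CI of ``metric_fn(labels, scores)``.

    Rows are resampled with replacement ``n_reps`` times; the CI is the
    (1 ± level)/2 percentile pair of the recomputed metric. Degenerate
    resamples (where the metric raises) are skipped and counted; more
    than 50% degenerate raises. ``metric_fn=binary_auc`` uses a
    vectorized rank-based path.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    n = labels.size
    estimate = float(metric_fn(labels, scores))
    alpha = (1.0 - level) / 2.0

    if metric_fn is binary_auc:
        idx = rng.integers(0, n, size=(n_reps, n))
        y = (labels[idx] > 0).astype(float)
        n_pos = y.sum(axis=1)
        ok = (n_pos > 0) & (n_pos < n)
        vals = _vectorized_auc(y[ok], scores[idx][ok])
        n_degenerate = int(n_reps - ok.sum())
    else:
        vals_list = []
        n_degenerate = 0
        for _ in range(n_reps):
            idx = rng.integers(0, n, size=n)
            try:
                vals_list.append(float(metric_fn(labels[idx], scores[idx])))
            except ValueError:
                n_degenerate += 1
        vals = np.asarray(vals_list)
    if n_degenerate > 0.5 * n_reps:
        raise RuntimeError(
            f"{n_degenerate}/{n_reps} degenerate bootstrap resamples")
    lower, upper = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(estimate=estimate, lower=float(lower),
                       upper=float(upper), n_reps=n_reps,
                       n_degenerate=n_degenerate)


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples (both n ≤ 20), normal
    approximation with tie and continuity corrections otherwise.
    Returns U for the first group.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def group_stats(
    table: pd.DataFrame,
    metric: str,
    classes: list[int],
    label_column: str = "histology_class",
    ddof: int = 1,
    round_percent: bool = True,
) -> dict:
    """Per-class mean ± SD and pairwise percent differences.

    Percent difference of class i vs j is 100·(mᵢ − mⱼ)/mⱼ, rounded to
    integer percent by default. ``ddof=1`` gives the sample SD; pass 0
    for the population convention.
    """
    out: dict = {"means": {}, "sds": {}, "percent_differences": {}}
    for cls in classes:
        vals = table.loc[table[label_column] == cls, metric].to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"class {cls}: need at least 2 values")
        out["means"][cls] = float(vals.mean())
        out["sds"][cls] = float(np.std(vals, ddof=ddof))
    for ci in classes:
        for cj in classes:
            if ci == cj:
                continue
            pct = percent_difference(out["means"][ci], out["means"][cj],
                                     rounded=round_percent)
            out["percent_differences"][(ci, cj)] = pct
    return out


def percent_difference(m1: float, m2: float, rounded: bool = True) -> float:
    """100 · (m1 − m2) / m2, optionally rounded to integer percent."""
    pct = 100.0 * (m1 - m2) / m2
    return float(round(pct)) if rounded else float(pct)


def evaluate_multiclass(
    true_labels: np.ndarray,
    proba: np.ndarray,
    class_order: tuple[int, ...],
    predicted_labels: np.ndarray | None = None,
    bootstrap_reps: int = 0,
    seed: int = 0,
) -> EvalReport:
    """Full one-vs-rest evaluation of a probabilistic classifier.

    Produces the confusion matrix, per-class ROC/PR curves with F1 at
    the hard labels, Youden operating points, and (when
    ``bootstrap_reps`` > 0) percentile-bootstrap AUC CIs.
    """
    true_labels = np.asarray(true_labels).ravel()
    if predicted_labels is None:
        predicted_labels = np.asarray(class_order)[np.asarray(proba).argmax(axis=1)]
    cm = confusion(true_labels, predicted_labels, classes=class_order)
    curves: dict[int, CurveSet] = {}
    youden: dict[int, dict[str, float]] = {}
    cis: dict[int, BootstrapCI] = {}
    for cls in class_order:
        if (true_labels == cls).sum() == 0:
            continue
        cs = pr_ovr(proba, true_labels, cls,
                    predicted_labels=predicted_labels, class_order=class_order)
        curves[cls] = cs
        youden[cls] = youden_point(cs)
        if bootstrap_reps > 0:
            s = _class_scores(proba, cls, class_order)
            cis[cls] = bootstrap_ci(binary_auc, _binarize(true_labels, cls), s,
                                    n_reps=bootstrap_reps, seed=seed + cls)
    return EvalReport(confusion=cm, curves=curves, auc_cis=cis, youden=youden)
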