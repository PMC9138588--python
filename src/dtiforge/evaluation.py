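"""Metrics, ROC/AUC, and five-fold cross-validation.

The metric suite is the standard confusion-matrix family

    Accu = (TP + TN) / (TP + TN + FP + FN)
    Sen  = TP / (TP + FN)
    Spec = TN / (TN + FP)
    Prec = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

plus the area under the ROC curve (sensitivity vs 1 - specificity
across all score thresholds, tied scores grouped into one step,
trapezoidal integration — equivalent to the Mann-Whitney statistic
with half credit for ties).

Cross-validation shuffles the samples with a seeded generator and
splits them into five disjoint folds of size floor(n/5), the first
n mod 5 folds taking one extra sample.  Each fold is tested once
against a model trained on the other four; per-fold reports are
aggregated as mean +/- sample standard deviation (n-1 denominator).

A metric whose denominator is zero on some fold (e.g. a single-class
fold) is reported as None and skipped in aggregation rather than
poisoning the whole report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import math

import numpy as np

from .errors import MetricUndefinedError, ShapeError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCCurve",
    "CVResult",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_auc",
    "five_fold_cv",
    "aggregate",
]

METRIC_NAMES = ("accu", "sen", "spec", "prec", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.TP + self.TN + self.FP + self.FN < 1:
            raise ValueError("confusion counts sum to zero")


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation: five confusion metrics + AUC (None = undefined)."""

    accu: float | None = None
    sen: float | None = None
    spec: float | None = None
    prec: float | None = None
    mcc: float | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (1 - specificity, sensitivity) points from (0,0) to (1,1)."""

    points: list[tuple[float, float]]

    def to_tsv(self) -> str:
        lines = ["fpr\ttpr"]
        lines += [f"{x:.6g}\t{y:.6g}" for x, y in self.points]
        return "\n".join(lines) + "\n"


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    mean_report: MetricsReport
    std_report: MetricsReport

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean": self.mean_report.to_dict(),
            "std": self.std_report.to_dict(),
        }


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Confusion metrics; any zero-denominator metric comes back None."""
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN

    def ratio(num, den):
        return num / den if den > 0 else None

    mcc_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den_sq) if mcc_den_sq > 0 else None
    return MetricsReport(
        accu=ratio(tp + tn, tp + tn + fp + fn),
        sen=ratio(tp, tp + fn),
        spec=ratio(tn, tn + fp),
        prec=ratio(tp, tp + fp),
        mcc=mcc,
        auc=None,
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[ROCCurve, float]:
    """ROC curve and trapezoidal AUC over grouped score thresholds.

    Thresholds sweep the distinct score values from high to low; all
    samples tied at one value enter the curve in a single step, so the
    trapezoid across the step gives ties half credit, matching the
    Mann-Whitney U / (n+ * n-) statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ShapeError("scores and labels must be equal-length 1-D")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("AUC undefined: only one class present")

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a new distinct score value ends
    boundaries = np.nonzero(np.diff(s))[0]
    step_ends = np.append(boundaries, len(s) - 1)
    tp_cum = np.cumsum(y == 1)[step_ends]
    fp_cum = np.cumsum(y == 0)[step_ends]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    curve = ROCCurve(points=list(zip(fpr.tolist(), tpr.tolist())))
    return curve, auc


def _fold_slices(n: int, n_folds: int = 5) -> list[np.ndarray]:
    sizes = [n // n_folds + (1 if i < n % n_folds else 0) for i in range(n_folds)]
    edges = np.cumsum([0] + sizes)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_folds)]


def five_fold_cv(
    X,
    y: Sequence[int],
    trainer: Callable,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """Five-fold cross-validation of a classifier factory.

    ``trainer(X_train, y_train)`` must return a scorer: a callable
    mapping test samples to continuous decision scores (label 1 iff
    score > 0).  The trainer never sees test-fold labels.  ``X`` may be
    a numpy array or any sequence supporting list indexing.

    Folds come from a seeded shuffle (optionally stratified by class):
    sizes floor(n/5), with the first n mod 5 folds one larger.
    """
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 10:
        raise ShapeError("five-fold CV needs at least 10 samples")
    if len(set(y.tolist())) < 2:
        raise ShapeError("both classes must be present")

    rng = np.random.default_rng(seed)
    if stratified:
        # round-robin deal within each shuffled class keeps folds balanced
        fold_of = np.empty(n, dtype=int)
        for c in (0, 1):
            idx = rng.permutation(np.nonzero(y == c)[0])
            fold_of[idx] = np.arange(len(idx)) % 5
        folds = [np.nonzero(fold_of == f)[0] for f in range(5)]
    else:
        perm = rng.permutation(n)
        folds = [perm[lo:hi] for lo, hi in _fold_slices(n)]

    is_array = isinstance(X, np.ndarray)

    def take(idx):
        return X[idx] if is_array else [X[int(i)] for i in idx]

    all_idx = np.arange(n)
    reports: list[MetricsReport] = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        scorer = trainer(take(train_idx), y[train_idx])
        scores = np.asarray(scorer(take(test_idx)), dtype=float)
        y_test = y[test_idx]
        preds = (scores > 0).astype(int)
        report = compute_metrics(confusion_from_predictions(y_test, preds))
        try:
            _, auc = roc_auc(scores, y_test)
        except MetricUndefinedError:
            auc = None
        reports.append(MetricsReport(**{**report.to_dict(), "auc": auc}))

    mean_r, std_r = aggregate(reports)
    return CVResult(fold_reports=reports, mean_report=mean_r, std_report=std_r)


def aggregate(fold_reports):
    """Mean and sample standard deviation (n-1 denominator) per metric.

    Accepts either a sequence of :class:`MetricsReport` (aggregated
    per metric, skipping None entries) or a plain sequence of numbers
    (returning two floats).  The n-1 denominator is what reproduces
    published mean +/- deviation rows from their per-fold values.
    """
    seq = list(fold_reports)
    if seq and isinstance(seq[0], MetricsReport):
        means, stds = {}, {}
        for name in METRIC_NAMES:
            vals = [getattr(r, name) for r in seq if getattr(r, name) is not None]
            if not vals:
                means[name] = stds[name] = None
            else:
                means[name] = float(np.mean(vals))
                stds[name] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return MetricsReport(**means), MetricsReport(**stds)
    vals = np.asarray(seq, dtype=float)
    return float(np.mean(vals)), float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
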