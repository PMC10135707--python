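"""Classification metrics for the difficulty classifier.

All scalar metrics derive from a 2x2 confusion matrix in which the positive
class is the *difficult* pelvis (label 1).  Ranked metrics (ROC/AUC,
precision-recall/AP) are computed from continuous prediction scores via
scikit-learn.  ``solve_confusion_from_metrics`` inverts the scalar metric
definitions by exhaustive integer enumeration, which lets a printed results
table be audited back to the unique confusion matrix that produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "pr_ap",
    "aggregate_folds",
    "solve_confusion_from_metrics",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round half away from zero (presentation rounding used in clinical tables)."""
    scale = 10.0**decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts; positive class = difficult (label 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion-matrix cells must be nonnegative")
        if sum(counts) == 0:
            raise ValueError("confusion matrix must count at least one case")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Scalar metric values; ``None`` marks an undefined metric (never 0)."""

    accuracy: Optional[float] = None
    precision: Optional[float] = None
    specificity: Optional[float] = None
    recall: Optional[float] = None
    f1: Optional[float] = None
    auc: Optional[float] = None
    average_precision: Optional[float] = None

    def rounded(self, decimals: int = 3) -> "MetricReport":
        vals = {
            f.name: (None if getattr(self, f.name) is None else round_half_away(getattr(self, f.name), decimals))
            for f in fields(self)
        }
        return MetricReport(**vals)


def confusion(pred: Sequence[int], true: Sequence[int]) -> ConfusionMatrix:
    """Count the four confusion cells from binary predicted and true labels."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction and label vectors differ in length")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, precision, specificity, recall and F1 from a confusion matrix.

    A metric whose denominator is zero is reported as ``None`` rather than 0.
    """
    accuracy = (cm.tp + cm.tn) / cm.n
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    specificity = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return MetricReport(accuracy=accuracy, precision=precision, specificity=specificity, recall=recall, f1=f1)


def roc_auc(scores: Sequence[float], labels: Sequence[int]):
    """Trapezoidal ROC AUC (Mann-Whitney-equivalent tie handling) plus curve points.

    Returns ``(auc, fpr, tpr)``; ``auc`` is ``None`` when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        return None, None, None
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(roc_auc_score(labels, scores)), fpr, tpr


def pr_ap(scores: Sequence[float], labels: Sequence[int]):
    """Average precision (non-interpolated step sum) plus P-R curve points."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if int(np.sum(labels == 1)) == 0:
        return None, None, None
    prec, rec, _ = precision_recall_curve(labels, scores)
    return float(average_precision_score(labels, scores)), prec, rec


def aggregate_folds(reports: Sequence[MetricReport]) -> MetricReport:
    """Unweighted arithmetic mean of each metric across fold reports."""
    if len(reports) == 0:
        raise ValueError("need at least one report")
    out = {}
    for f in fields(MetricReport):
        vals = [getattr(r, f.name) for r in reports if getattr(r, f.name) is not None]
        out[f.name] = float(np.mean(vals)) if vals else None
    return MetricReport(**out)


def _rounds_to(value: float, target: float, decimals: int) -> bool:
    return round_half_away(value, decimals) == round_half_away(target, decimals)


def solve_confusion_from_metrics(
    n: int,
    precision: float,
    specificity: float,
    recall: float,
    f1: float,
    decimals: int = 3,
) -> list[ConfusionMatrix]:
    """All integer confusion matrices of size ``n`` whose metrics round to the given values.

    Exhaustive over every decomposition of ``n`` into (TP, FP, TN, FN); an empty
    list is a valid result.  Intended to audit printed results tables, so ``n``
    is restricted to at most 10^4.
    """
    if n > 10**4:
        raise ValueError("enumeration limited to n <= 1e4")
    hits: list[ConfusionMatrix] = []
    for pos in range(n + 1):  # pos = TP + FN
        for tp in range(pos + 1):
            fn = pos - tp
            if tp + fn > 0 and not _rounds_to(tp / (tp + fn), recall, decimals):
                continue
            for fp in range(n - pos + 1):
                tn = n - pos - fp
                if tp + fp == 0 or tn + fp == 0:
                    continue
                p = tp / (tp + fp)
                if not _rounds_to(p, precision, decimals):
                    continue
                if not _rounds_to(tn / (tn + fp), specificity, decimals):
                    continue
                r = tp / (tp + fn) if tp + fn > 0 else None
                if r is None or p + r == 0:
                    continue
                if not _rounds_to(2 * p * r / (p + r), f1, decimals):
                    continue
                hits.append(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
    return hits
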