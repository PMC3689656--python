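"""Confusion-matrix bookkeeping, Sn/Sp/Ac/MCC, and ROC curves.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Ac = (TP+TN)/(TP+FP+TN+FN), and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with MCC defined as 0 when any denominator factor vanishes (the
no-relationship convention extended to degenerate counts). Reported
percentages round half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / TN / FN counts for one binary evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sn, Sp, Ac in [0, 1] and MCC in [-1, 1]."""

    sn: float
    sp: float
    ac: float
    mcc: float


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN from 0/1 label vectors (1 = positive)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("label vectors must be equal-length 1-D arrays")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Compute Sn/Sp/Ac/MCC from confusion counts.

    Raises when a requested rate has a zero denominator (no positives for
    Sn, no negatives for Sp) rather than silently reporting 0.
    """
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    if pos == 0:
        raise ValueError("Sn undefined: no positive samples (TP + FN = 0)")
    if neg == 0:
        raise ValueError("Sp undefined: no negative samples (TN + FP = 0)")
    denom2 = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = 0.0 if denom2 == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom2)
    return MetricSet(
        sn=c.tp / pos,
        sp=c.tn / neg,
        ac=(c.tp + c.tn) / c.total,
        mcc=mcc,
    )


def mean_metrics(sets: list[MetricSet]) -> MetricSet:
    """Arithmetic mean of metric sets (e.g. across CV folds or datasets)."""
    if not sets:
        raise ValueError("no metric sets to average")
    return MetricSet(
        sn=float(np.mean([m.sn for m in sets])),
        sp=float(np.mean([m.sp for m in sets])),
        ac=float(np.mean([m.ac for m in sets])),
        mcc=float(np.mean([m.mcc for m in sets])),
    )


def as_percent(x: float, decimals: int = 2) -> float:
    """Proportion -> percentage, rounded half-up (97.973 -> 97.97)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ROCCurve:
    """Operating points (FPR, TPR) over score thresholds, plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(y_true, scores) -> ROCCurve:
    """ROC curve from positive-class scores (tied scores grouped), with
    trapezoid-rule AUC. Requires both classes present."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape or y_true.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D arrays")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, thr = _sk_roc_curve(y_true, scores)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))
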