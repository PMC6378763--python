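"""Confusion-matrix metrics, ROC construction and AUC.

A sample is called positive when its score reaches the decision threshold
(score >= t), so t = 0 is the all-positive corner of ROC space.  The ROC
curve is sampled at the 101 thresholds 0.00, 0.01, ..., 1.00 and the AUC is
the trapezoidal area under that sweep; sensitivity = TP/(TP+FN) and
specificity = TN/(TN+FP), with 0/0 ratios surfaced as NaN rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "confusion",
    "metrics",
    "roc",
    "auc",
    "ROC_THRESHOLDS",
]

#: the fixed threshold sweep: 0.00 to 1.00 in 0.01 steps
ROC_THRESHOLDS = np.round(np.arange(101) / 100.0, 2)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class RocCurve:
    """101 (threshold, FPR, TPR) points, thresholds ascending."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _as_arrays(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores ({scores.shape}) and labels ({labels.shape}) differ in length"
        )
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return scores, labels.astype(bool)


def confusion(scores, labels, threshold: float) -> ConfusionCounts:
    """Threshold scores at ``score >= threshold`` and count the four cells."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    scores, pos = _as_arrays(scores, labels)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); 0/0 cells come back as NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else float("nan")
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else float("nan")
    return accuracy, sensitivity, specificity


def roc(scores, labels) -> RocCurve:
    """Sweep the 101-point threshold grid and record (FPR, TPR) at each."""
    scores, pos = _as_arrays(scores, labels)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    fpr = np.empty(len(ROC_THRESHOLDS))
    tpr = np.empty(len(ROC_THRESHOLDS))
    for i, t in enumerate(ROC_THRESHOLDS):
        pred = scores >= t
        tpr[i] = np.sum(pred & pos) / n_pos
        fpr[i] = np.sum(pred & ~pos) / n_neg
    return RocCurve(thresholds=ROC_THRESHOLDS.copy(), fpr=fpr, tpr=tpr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the curve, integrating over FPR ascending.

    Along the threshold sweep FPR and TPR are both non-increasing, so
    reversing the sweep orders the curve by ascending FPR while keeping each
    (FPR, TPR) pair intact.
    """
    x = curve.fpr[::-1]
    y = curve.tpr[::-1]
    return float(np.trapezoid(y, x))
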