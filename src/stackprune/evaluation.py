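"""Test-set evaluation: confusion matrix, metric suite, ROC/AUC.

Balanced accuracy is defined as the exact mean of sensitivity and
specificity.  AUC is computed with the rank statistic (Mann-Whitney with
half-credit for ties), which equals the trapezoidal area under the ROC
curve; both routes are exposed so they can be checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve


@dataclass
class MetricsReport:
    """Confusion counts plus the derived proportions and the ROC curve."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float | None = None
    roc_points: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        out = {
            "accuracy": round_half_away(self.accuracy, ndigits),
            "sensitivity": round_half_away(self.sensitivity, ndigits),
            "specificity": round_half_away(self.specificity, ndigits),
            "balanced_accuracy": round_half_away(self.balanced_accuracy, ndigits),
        }
        if self.auc is not None:
            out["auc"] = round_half_away(self.auc, ndigits)
        return out


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round with halves away from zero (0.7605 -> 0.761), unlike the
    banker's rounding of built-in :func:`round`."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def confusion_at_threshold(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """Tally (tp, fp, tn, fn); a probability equal to the threshold counts
    as a positive prediction."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must be aligned")
    pred = probs >= threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    return tp, fp, tn, fn


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Accuracy, sensitivity, specificity, and their balanced mean."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fn == 0:
        raise ValueError("no positive cases: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative cases: specificity undefined")
    n = tp + fp + tn + fn
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
    )


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """The exact mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def roc_auc(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC via the rank statistic plus the ROC polyline.

    Ties receive half credit, making the statistic identical to the
    trapezoidal area under the ROC curve.  Returns ``(auc, points)`` with
    points as an ordered (FPR, TPR) array from (0,0) to (1,1).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = rankdata(probs)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, probs)
    points = np.column_stack([fpr, tpr])
    return float(auc), points


def evaluate_predictions(
    probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Full metric suite at a classification threshold."""
    tp, fp, tn, fn = confusion_at_threshold(probs, labels, threshold)
    report = metrics_from_confusion(tp, fp, tn, fn)
    report.auc, report.roc_points = roc_auc(probs, labels)
    return report
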