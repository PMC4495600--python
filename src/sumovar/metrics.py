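"""Confusion-matrix metrics and ROC/AUC.

Accuracy, sensitivity and specificity are reported as percentages (the raw
fractions are available via the ``*_fraction`` variants); a zero denominator
yields NaN, never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.TP + self.FN

    @property
    def negatives(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def accuracy_fraction(c: ConfusionCounts) -> float:
    if c.total == 0:
        return math.nan
    return (c.TP + c.TN) / c.total


def sensitivity_fraction(c: ConfusionCounts) -> float:
    if c.positives == 0:
        return math.nan
    return c.TP / c.positives


def specificity_fraction(c: ConfusionCounts) -> float:
    if c.negatives == 0:
        return math.nan
    return c.TN / c.negatives


def accuracy(c: ConfusionCounts) -> float:
    """Percent of correct predictions over all positives and negatives."""
    return 100.0 * accuracy_fraction(c)


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate, as a percentage."""
    return 100.0 * sensitivity_fraction(c)


def specificity(c: ConfusionCounts) -> float:
    """True negative rate, as a percentage."""
    return 100.0 * specificity_fraction(c)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; NaN if any marginal is 0."""
    denom = ((c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN))
    if denom == 0:
        return math.nan
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def confusion_from_scores(scores, labels, cutoff: float) -> ConfusionCounts:
    """Counts at a probability cutoff; a score >= cutoff is a positive call."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    calls = s >= cutoff
    pos = y == 1
    return ConfusionCounts(
        TP=int((calls & pos).sum()),
        FN=int((~calls & pos).sum()),
        TN=int((~calls & ~pos).sum()),
        FP=int((calls & ~pos).sum()),
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR, thresholds) at every distinct score cutoff.

    Tied scores are grouped into a single cutoff. Labels are +1/-1 (or
    truthy/falsy); both classes must be present.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels) == 1 if set(np.unique(labels)) <= {-1, 1} else np.asarray(labels, bool)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep only the last index of each tied-score group
    distinct = np.nonzero(np.diff(s_sorted, append=-np.inf))[0]
    tpr = np.concatenate([[0.0], tps[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fps[distinct] / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[distinct]])
    return fpr, tpr, thresholds


def auc(fpr, tpr) -> float:
    """Area under the ROC curve by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


def roc_auc(scores, labels) -> float:
    fpr, tpr, _ = roc_curve(scores, labels)
    return auc(fpr, tpr)
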