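"""Diagnostic-test statistics for the clinical comparison layer.

Covers the small battery used when comparing an imaging test against an
invasive gold standard: Pearson chi-square on 2x2 positive/negative count
tables, the independent-samples (pooled-variance) t-test for continuous
measurements, ROC curves with trapezoid AUC, sensitivity and misdiagnosis
rate (false-positive rate) from a confusion table, and the knee anatomical
ratio indices (intercondylar notch width index, eminence/notch ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .kspace import ValidationError

__all__ = [
    "DiagnosticCounts",
    "ConfusionCounts",
    "AnatomicalParams",
    "chi_square_2x2",
    "independent_t_test",
    "sensitivity_misdiagnosis",
    "roc_auc",
    "notch_width_index",
    "eminence_notch_ratio",
]


@dataclass(frozen=True)
class DiagnosticCounts:
    """Positive/negative tallies of one diagnostic method."""

    positives: int
    negatives: int

    def __post_init__(self) -> None:
        if self.positives < 0 or self.negatives < 0:
            raise ValidationError("counts must be nonnegative")
        if self.positives + self.negatives == 0:
            raise ValidationError("need at least one observation")

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValidationError("confusion table must be nonempty")


@dataclass(frozen=True)
class AnatomicalParams:
    """Knee measurements (mm) entering the ratio indices."""

    bicondylar_width: float
    notch_width: float
    eminence_width: float
    eminence_height_medial: float = 0.0
    eminence_height_lateral: float = 0.0

    def __post_init__(self) -> None:
        if self.bicondylar_width <= 0 or self.notch_width <= 0:
            raise ValidationError("widths must be positive")


def chi_square_2x2(
    a: DiagnosticCounts, b: DiagnosticCounts, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) comparing two positive/negative tallies.

    Yates continuity correction is off by default (appropriate for large
    tables) and available via ``yates=True``.
    """
    table = np.array(
        [[a.positives, a.negatives], [b.positives, b.negatives]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("chi-square table has a zero marginal")
    res = sps.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def independent_t_test(x, y) -> tuple[float, float]:
    """Two-sample pooled-variance t-test, two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs at least two observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("samples must be finite")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        raise ValidationError("both samples are constant with unequal means")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def sensitivity_misdiagnosis(c: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and misdiagnosis rate fp/(fp+tn).

    The misdiagnosis rate is the false-positive rate, i.e. 1 - specificity.
    """
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValidationError("need at least one actual positive and negative")
    return c.tp / (c.tp + c.fn), c.fp / (c.fp + c.tn)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve (threshold sweep, ties grouped) and trapezoid AUC.

    Returns the ROC as an array of (FPR, TPR) points from (0,0) to (1,1)
    and the trapezoid-rule area, which equals the probability that a random
    positive outscores a random negative (ties counted one half).  For a
    binary test the curve degenerates to (0,0)-(FPR,TPR)-(1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have matching length")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValidationError("labels must contain both classes")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def notch_width_index(notch_width: float, bicondylar_width: float) -> float:
    """Intercondylar notch width / femoral bicondylar width (same level)."""
    if bicondylar_width <= 0:
        raise ValidationError("bicondylar width must be positive")
    if notch_width < 0:
        raise ValidationError("notch width must be nonnegative")
    return notch_width / bicondylar_width


def eminence_notch_ratio(eminence_width: float, notch_width: float) -> float:
    """Tibial intercondylar eminence width / intercondylar notch width."""
    if notch_width <= 0:
        raise ValidationError("notch width must be positive")
    if eminence_width < 0:
        raise ValidationError("eminence width must be nonnegative")
    return eminence_width / notch_width
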