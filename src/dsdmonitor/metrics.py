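"""Threshold-based evaluation of per-frame DSD probability scores.

A frame with score >= cutoff is called DSD-positive (the equality case is
a documented convention; the definitions of TP/FP/TN/FN otherwise follow
the usual diagnostic-test layout with DSD as the positive class).  The ROC
curve is traced over the unique observed scores, AUC is the trapezoid
area, and the operating cutoff is the score maximising the Youden index
J = sensitivity + specificity - 1, with ties broken toward the smallest
qualifying threshold (earlier DSD detection).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "CutoffResult",
    "confusion_at_cutoff",
    "metrics",
    "roc_curve",
    "youden_cutoff",
    "percent",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RocCurve:
    """Operating points ordered from the strictest threshold down.

    ``thresholds[0]`` is an ``inf`` sentinel giving the (0, 0) corner; the
    final point is (1, 1).  ``fpr``/``tpr`` are monotone non-decreasing.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if s.size == 0:
        raise ValueError("empty input")
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return s, y.astype(np.int64)


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    """Counts with positive = score >= cutoff, DSD (label 1) positive class."""
    s, y = _check_scores_labels(scores, labels)
    pos = s >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
        tn=int(np.sum(~pos & (y == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV and NPV as fractions in [0, 1].

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never as 0.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.fp + c.tn),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


def percent(x: float | None, decimals: int = 1) -> float | None:
    """Fraction -> percentage rounded half-up to ``decimals`` places."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def roc_curve(scores, labels) -> RocCurve:
    """ROC over the unique observed scores, with trapezoid AUC.

    Tied scores collapse onto one operating point.  Requires both classes.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    cum_tp = np.cumsum(y_sorted == 1)
    cum_fp = np.cumsum(y_sorted == 0)
    # keep the last index of each tied-score group (positive = score >= t)
    last = np.r_[np.diff(s_sorted) != 0, True]
    thresholds = np.r_[np.inf, s_sorted[last]]
    tpr = np.r_[0.0, cum_tp[last] / n_pos]
    fpr = np.r_[0.0, cum_fp[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def youden_cutoff(scores, labels) -> CutoffResult:
    """Cutoff maximising J = sensitivity + specificity - 1.

    Candidate cutoffs are the unique observed scores; among ties the
    smallest qualifying threshold is returned.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Youden cutoff needs both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    last = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted == 1)[last]
    fp = np.cumsum(y_sorted == 0)[last]
    thresholds = s_sorted[last]
    # J = tp/n_pos - fp/n_neg compared exactly via the integer
    # tp*n_neg - fp*n_pos, so the tie rule is free of float round-off.
    j_scaled = tp.astype(np.int64) * n_neg - fp.astype(np.int64) * n_pos
    ties = np.where(j_scaled == j_scaled.max())[0]
    best = ties[np.argmin(thresholds[ties])]
    sens = tp[best] / n_pos
    spec = 1.0 - fp[best] / n_neg
    return CutoffResult(
        cutoff=float(thresholds[best]),
        youden_j=float(sens + spec - 1.0),
        sensitivity=float(sens),
        specificity=float(spec),
    )
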