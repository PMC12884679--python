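"""Confusion-matrix metrics, ROC/AUC and overlap scores."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .labels import ARTERY, UNDEFINED, VEIN

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_masks",
    "compute_metrics",
    "roc_auc",
    "dice_coefficient",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    """Six closed-form metrics; a zero-denominator metric is None."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    mcc: float | None
    auc: float | None = None

    def as_percent(self, ndigits: int = 2) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = None if v is None else round(100.0 * v, ndigits)
        return out


def confusion_from_masks(pred: np.ndarray, truth: np.ndarray,
                         positive_label: int | None = None) -> ConfusionMatrix:
    """Pixelwise confusion counts.

    For binary masks, 1 is the positive class.  For artery/vein label maps
    pass ``positive_label`` (default artery); undefined pixels are excluded
    and only vessel pixels (artery or vein in the truth) are counted.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if positive_label is None and set(np.unique(truth)) <= {0, 1}:
        p = pred.astype(bool)
        t = truth.astype(bool)
    else:
        pos = ARTERY if positive_label is None else positive_label
        neg = VEIN if pos == ARTERY else ARTERY
        keep = np.isin(truth, (pos, neg)) & (pred != UNDEFINED)
        p = pred[keep] == pos
        t = truth[keep] == pos
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_div(num: float, den: float, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
        return None
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision, F1 and MCC from raw
    confusion counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    acc = _safe_div(tp + tn, cm.total, "accuracy")
    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, tn + fp, "specificity")
    prec = _safe_div(tp, tp + fp, "precision")
    if prec is None or sens is None or (prec + sens) == 0:
        warnings.warn("f1 undefined", stacklevel=2)
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, math.sqrt(denom), "mcc") \
        if denom > 0 else _safe_div(1, 0, "mcc")
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         precision=prec, f1=f1, mcc=mcc)


def roc_auc(scores: np.ndarray, truth: np.ndarray):
    """ROC curve by a sweep over the unique score thresholds, and the
    trapezoidal area under it.

    Returns (curve, auc) where curve rows are (fpr, tpr, threshold).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    # cumulative counts at each distinct threshold
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.concatenate([distinct, [s.size - 1]])
    tps = np.cumsum(t)[cut]
    fps = np.cumsum(~t)[cut]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thr = np.concatenate([[np.inf], s[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([fpr, tpr, thr])
    return curve, auc


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.sum(a & b)) / float(denom)
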