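"""Segmentation evaluation: per-class IoU and mean IoU.

For each organ class c the predicted point set and the true point set are
compared via one-vs-rest tallies (TP, FP, FN) of the full confusion matrix:

    IoU_c = TP_c / (TP_c + FP_c + FN_c)        (|A ∩ B| / |A ∪ B|)
    MIoU  = mean over classes with non-empty union

A class absent from both prediction and truth has an undefined IoU and is
excluded from the mean with a warning.  A ``literal`` variant with
denominator TP + FP − FN is retained for auditability; it is not a true
intersection-over-union (it can exceed 1 or divide by zero) and is never
used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix

from .cloud import CLASS_NAMES, N_CLASSES
from .errors import EvaluationError, ValidationError

__all__ = ["ConfusionCounts", "confusion_counts", "iou_miou"]


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest tallies derived from a k×k confusion matrix."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    k: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if self.k != other.k:
            raise ValidationError("cannot add counts with different k")
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.k)

    @property
    def total(self) -> int:
        return int(self.tp.sum() + self.fn.sum())


def confusion_counts(pred_labels, true_labels, k: int = N_CLASSES) -> ConfusionCounts:
    """Tally TP/FP/FN per class from predicted and true label vectors."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValidationError(
            f"label vectors must be equal-length 1-d; got {pred.shape} vs {true.shape}")
    cm = confusion_matrix(true, pred, labels=np.arange(k))
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return ConfusionCounts(tp.astype(np.int64), fp.astype(np.int64),
                           fn.astype(np.int64), k)


def iou_miou(counts: ConfusionCounts,
             literal: bool = False) -> tuple[np.ndarray, float]:
    """Per-class IoU and their mean.

    Returns ``(iou, miou)`` where ``iou`` has NaN for classes with an empty
    union (excluded from the mean).  Raises if every class is undefined.
    """
    union = counts.tp + counts.fp + counts.fn
    denom = counts.tp + counts.fp - counts.fn if literal else union
    iou = np.full(counts.k, np.nan)
    defined = union > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        iou[defined] = counts.tp[defined] / denom[defined]
    if not defined.any():
        raise EvaluationError("IoU undefined for every class (no points?)")
    if not defined.all():
        missing = [CLASS_NAMES[c] if c < len(CLASS_NAMES) else str(c)
                   for c in np.nonzero(~defined)[0]]
        warnings.warn(f"classes with empty union excluded from MIoU: {missing}")
    miou = float(np.nanmean(iou[defined].astype(float))) if defined.any() else np.nan
    return iou, float(np.mean(iou[defined]))
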