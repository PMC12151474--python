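"""Segmentation loss (BCE + dice) and evaluation metrics.

Training minimises ``Loss = L_BCE + L_dice`` on the predicted foreground
probability map:

    L_BCE  = -(1/N) * sum_i [ y_i ln p_i + (1 - y_i) ln(1 - p_i) ]
    L_dice = 1 - (2 |X ∩ Y| + smooth) / (|X| + |Y| + smooth)

where the dice loss is the *soft* form (|X ∩ Y| = sum p*y, |Y| = sum p),
``smooth`` keeps empty-vs-empty well defined, and probabilities are clipped
to [eps, 1 - eps] before the logarithms.

Reported metrics come from hard (0.5-thresholded) masks via per-pixel
confusion counts:

    dice = 2 TP / ((TP + FN) + (TP + FP))      precision = TP / (TP + FP)
    recall = TP / (TP + FN)                    IOU = TP / (FP + TP + FN)

When a denominator vanishes the metric is 1 if the prediction task was
trivially satisfied (TP = FP = FN = 0, e.g. a plaque-free image predicted
plaque-free) and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, clip

__all__ = ["EPSILON", "SMOOTH", "ConfusionCounts", "bce_loss", "dice_loss",
           "combined_loss", "confusion", "dice_coef", "precision", "recall",
           "iou", "evaluate_masks", "soft_loss_tensor", "MetricsReport"]

EPSILON = 1e-7   # probability clipping before logarithms
SMOOTH = 1.0     # dice smoothing constant


def _as_float(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty pixel batch")
    return a


def bce_loss(p, y, eps: float = EPSILON) -> float:
    """Mean binary cross-entropy over a pixel batch."""
    p, y = _as_float(p), _as_float(y)
    if p.shape != y.shape:
        raise ValueError("probability and label shapes differ")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_loss(pred, truth, smooth: float = SMOOTH) -> float:
    """Soft dice loss, 1 - (2 sum(p*y) + s) / (sum(p) + sum(y) + s)."""
    pred, truth = _as_float(pred), _as_float(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if smooth <= 0:
        raise ValueError("smooth must be positive")
    inter = float((pred * truth).sum())
    return 1.0 - (2.0 * inter + smooth) / (pred.sum() + truth.sum() + smooth)


def combined_loss(pred, truth, smooth: float = SMOOTH,
                  eps: float = EPSILON) -> float:
    """BCE + dice, the training objective."""
    return bce_loss(pred, truth, eps) + dice_loss(pred, truth, smooth)


def soft_loss_tensor(prob: Tensor, truth: np.ndarray,
                     smooth: float = SMOOTH, eps: float = EPSILON) -> Tensor:
    """Differentiable BCE + soft-dice on (N, H, W) probability tensors.

    Per-image dice averaged over the batch; BCE averaged over all pixels.
    Matches :func:`combined_loss` on a single image.
    """
    n = prob.shape[0]
    y = Tensor(truth.astype(np.float32))
    p = clip(prob, eps, 1.0 - eps)
    bce = -(y * p.log() + (1.0 - y) * (1.0 - p).log()).mean()
    npix = int(np.prod(prob.shape[1:]))
    pf = prob.reshape(n, npix)
    yf = y.reshape(n, npix)
    inter = (pf * yf).sum(axis=1)
    dice = 1.0 - (2.0 * inter + smooth) / (pf.sum(axis=1) + yf.sum(axis=1) + smooth)
    return bce + dice.mean()


# ---------------------------------------------------------------------------
# confusion counts and the four metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel TP / TN / FP / FN tallies."""
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    """Tally pixelwise agreement of two binary masks."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    if not (np.isin(p, (0, 1)).all() and np.isin(t, (0, 1)).all()):
        raise ValueError("masks must be binary (0/1)")
    p, t = p.astype(bool), t.astype(bool)
    return ConfusionCounts(tp=int((p & t).sum()), tn=int((~p & ~t).sum()),
                           fp=int((p & ~t).sum()), fn=int((~p & t).sum()))


def _ratio(num: int, den: int, c: ConfusionCounts) -> float:
    if den == 0:
        return 1.0 if (c.tp == c.fp == c.fn == 0) else 0.0
    return num / den


def dice_coef(c: ConfusionCounts) -> float:
    """2 TP / ((TP + FN) + (TP + FP))."""
    return _ratio(2 * c.tp, (c.tp + c.fn) + (c.tp + c.fp), c)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, c)


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, c)


def iou(c: ConfusionCounts) -> float:
    """TP / (FP + TP + FN)."""
    return _ratio(c.tp, c.fp + c.tp + c.fn, c)


def evaluate_masks(pred_mask, true_mask) -> dict[str, float]:
    """All four metrics of one predicted mask against its ground truth."""
    c = confusion(pred_mask, true_mask)
    return {"dice": dice_coef(c), "precision": precision(c),
            "recall": recall(c), "iou": iou(c)}


@dataclass
class MetricsReport:
    """Image-wise metrics plus their mean (primary) and pooled-pixel twin."""

    per_image: list[dict[str, float]]
    pooled: ConfusionCounts

    @classmethod
    def from_pairs(cls, pairs) -> "MetricsReport":
        per_image, tp, tn, fp, fn = [], 0, 0, 0, 0
        for pred, true in pairs:
            c = confusion(pred, true)
            tp, tn, fp, fn = tp + c.tp, tn + c.tn, fp + c.fp, fn + c.fn
            per_image.append({"dice": dice_coef(c), "precision": precision(c),
                              "recall": recall(c), "iou": iou(c)})
        return cls(per_image=per_image,
                   pooled=ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))

    def mean(self) -> dict[str, float]:
        keys = ("dice", "precision", "recall", "iou")
        return {k: float(np.mean([m[k] for m in self.per_image])) for k in keys}

    def pooled_metrics(self) -> dict[str, float]:
        c = self.pooled
        return {"dice": dice_coef(c), "precision": precision(c),
                "recall": recall(c), "iou": iou(c)}
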