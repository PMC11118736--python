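"""Dice loss family and segmentation evaluation metrics.

The training loss is the smoothed Dice complement

    DC(y, p)  = (kappa + 2*sum(y*p)) / (kappa + sum(y*y) + sum(p*p))
    DCL(y, p) = 1 - DC(y, p)

with kappa = 1 by default; the denominator uses the squared-sum form,
which coincides with the count form on binary masks.  The smoothing
makes the empty-vs-empty case well defined (DC = kappa/kappa = 1).  An
optional per-sample class weight W is ADDED to the loss (DCLW = DCL +
W): it shifts the reported loss without altering its gradient.

Evaluation metrics (Dice, precision, recall, F1) are computed per image
on masks binarized at 0.5 and averaged over the evaluation set.
Degenerate denominators (no predicted or no true positives) yield 0
with a logged warning rather than an error, so batch evaluation never
aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad

log = logging.getLogger(__name__)


@dataclass
class LossConfig:
    kappa: float = 1.0
    alpha: float = 1.1
    use_weight_penalty: bool = True

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")


@dataclass
class MetricsReport:
    dice: float
    f1: float
    precision: float
    recall: float
    n_samples: int = 1

    def __post_init__(self):
        for name in ("dice", "f1", "precision", "recall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def _check_shapes(y_true, y_pred):
    y_true, y_pred = np.asarray(y_true, dtype=float), np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    return y_true, y_pred


def dice_coefficient(y_true, y_pred, kappa=1.0):
    """Smoothed Dice overlap; in (0, 1], equal masks give exactly 1."""
    y_true, y_pred = _check_shapes(y_true, y_pred)
    num = kappa + 2.0 * float((y_true * y_pred).sum())
    den = kappa + float((y_true * y_true).sum()) + float((y_pred * y_pred).sum())
    return num / den


def dice_loss(y_true, y_pred, kappa=1.0):
    return 1.0 - dice_coefficient(y_true, y_pred, kappa)


def weighted_dice_loss(y_true, y_pred, kappa=1.0, W=0.0):
    """Dice loss plus the additive class-weight penalty W."""
    return dice_loss(y_true, y_pred, kappa) + W


def dice_loss_tensor(y_true, y_pred, kappa=1.0, W=0.0):
    """Autodiff Dice loss over a batch of probability maps.

    y_pred: Tensor (N, 1, H, W); y_true: array broadcastable to it.
    Dice is computed per sample and the complements averaged; W (scalar
    or per-sample array) is added as a constant.
    """
    y = np.asarray(y_true, dtype=float).reshape(y_pred.shape)
    inter = ad.tsum(ad.mul(y_pred, y), axis=(1, 2, 3))
    pp = ad.tsum(ad.mul(y_pred, y_pred), axis=(1, 2, 3))
    tt = (y * y).sum(axis=(1, 2, 3))
    dc = ad.div(ad.add(ad.mul(inter, 2.0), kappa), ad.add(ad.add(pp, tt), kappa))
    dcl = ad.tmean(ad.add(ad.mul(dc, -1.0), 1.0))
    w_mean = float(np.mean(W))
    return ad.add(dcl, w_mean)


def confusion_metrics(y_true, y_pred_binary, kappa=1.0):
    """Precision, recall, F1 and smoothed Dice from pixel counts."""
    y_true, y_pred = _check_shapes(y_true, y_pred_binary)
    for name, arr in (("y_true", y_true), ("y_pred_binary", y_pred)):
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise ValueError(f"{name} must be binary")
    tp = float((y_true * y_pred).sum())
    fp = float(((1 - y_true) * y_pred).sum())
    fn = float((y_true * (1 - y_pred)).sum())
    if tp + fp == 0:
        log.warning("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        log.warning("no true positives; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        dice=dice_coefficient(y_true, y_pred, kappa),
        f1=f1,
        precision=precision,
        recall=recall,
        n_samples=1,
    )


def average_reports(reports):
    """Per-image metrics averaged over an evaluation set."""
    if not reports:
        raise ValueError("no reports to average")
    return MetricsReport(
        dice=float(np.mean([r.dice for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        n_samples=sum(r.n_samples for r in reports),
    )


def aggregate_folds(per_fold):
    """Cross-validation summary: per-metric "mean ± sd" on the % scale.

    Uses the sample standard deviation (ddof=1); requires >= 2 folds.
    Returns {metric: (mean_pct, sd_pct, "mean ± sd")}.
    """
    if len(per_fold) < 2:
        raise ValueError(f"need at least 2 folds, got {len(per_fold)}")
    out = {}
    for name in ("dice", "f1", "precision", "recall"):
        vals = np.array([getattr(r, name) for r in per_fold], dtype=float) * 100.0
        mean, sd = float(vals.mean()), float(vals.std(ddof=1))
        out[name] = (mean, sd, f"{mean:.1f} ± {sd:.1f}")
    return out
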