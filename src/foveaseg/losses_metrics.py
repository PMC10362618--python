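"""Focal training loss, the composite objective, and pixel overlap metrics.

The segmentation objective is L = L_focal + lambda * L_nHSIC: a focal loss on
the per-pixel foreground probability (foreground pixels are rare, so the
(1-p_t)^gamma factor concentrates the loss on hard pixels) plus the
channel-diversity penalty on the encoder's intrinsic feature maps.

Evaluation uses the five standard pixel metrics (IoU, Dice, sensitivity,
specificity, precision) computed from exact TP/FP/TN/FN tallies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .hghost import DEFAULT_EPSILON, l_nhsic_channels

PROB_CLAMP = 1e-7


@dataclass
class FocalParams:
    """alpha_t scales the per-pixel term, gamma focuses it on hard pixels,
    lam weighs the nHSIC diversity penalty in the composite loss."""

    alpha_t: float = 0.25
    gamma: float = 2.0
    lam: float = 0.75

    def __post_init__(self):
        if not 0 < self.alpha_t <= 1:
            raise ValueError("alpha_t must lie in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def focal_loss(p, y, params: FocalParams | None = None) -> Tensor:
    """Mean focal loss -alpha_t (1-p_t)^gamma log(p_t) over all pixels.

    ``p`` is the predicted foreground probability, ``y`` the binary mask;
    p_t = p where y = 1 and 1-p where y = 0.  Probabilities are clamped to
    [1e-7, 1-1e-7].  With gamma = 0 and alpha_t = 1 this is exactly the mean
    binary cross-entropy.
    """
    params = params or FocalParams()
    p = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    yd = np.asarray(y.data if isinstance(y, Tensor) else y)
    if yd.shape != p.shape:
        raise ValueError(f"mask shape {yd.shape} does not match prediction {p.shape}")
    if not np.isin(yd, (0, 1)).all():
        raise ValueError("mask must be binary")
    yd = yd.astype(p.data.dtype)
    pc = ad.clip(p, PROB_CLAMP, 1.0 - PROB_CLAMP)
    pt = pc * Tensor(yd) + (1.0 - pc) * Tensor(1.0 - yd)
    term = ad.power(1.0 - pt, params.gamma) * ad.log(pt) if params.gamma > 0 else ad.log(pt)
    return ad.tmean(term) * (-params.alpha_t)


@dataclass
class LossBreakdown:
    total: Tensor
    focal: Tensor
    nhsic: Tensor


def total_loss(
    p,
    y,
    intrinsics: list | None = None,
    params: FocalParams | None = None,
    eps: float = DEFAULT_EPSILON,
    nhsic_pool_hw: int = 8,
    nhsic_max_channels: int = 50,
) -> LossBreakdown:
    """Composite loss L = L_focal + lambda * L_nHSIC with logged components.

    ``intrinsics`` are NCHW intrinsic-map tensors of the monitored encoder
    layers; the channelwise nHSIC penalty is averaged across layers.  With
    lambda = 0 or no intrinsics the total equals the focal term.
    """
    params = params or FocalParams()
    focal = focal_loss(p, y, params)
    if params.lam > 0 and intrinsics:
        terms = [
            l_nhsic_channels(t, eps=eps, pool_hw=nhsic_pool_hw, max_channels=nhsic_max_channels)
            for t in intrinsics
        ]
        acc = terms[0]
        for t in terms[1:]:
            acc = acc + t
        nh = acc * (1.0 / len(terms))
    else:
        nh = Tensor(np.zeros((), dtype=np.float64))
    total = focal + nh * params.lam
    return LossBreakdown(total=total, focal=focal, nhsic=nh)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    """Exact pixel tallies; foreground (metastasis) is the positive class."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    for name, arr in (("prediction", pred), ("ground truth", gt)):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1, 255)).all():
            raise ValueError(f"{name} mask is not binary (values {vals[:5]}...)")
    pred = pred.astype(bool) if pred.max() <= 1 else pred > 127
    gt = gt.astype(bool) if gt.max() <= 1 else gt > 127
    tp = int(np.sum(pred & gt))
    fp = int(np.sum(pred & ~gt))
    fn = int(np.sum(~pred & gt))
    tn = int(np.sum(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_ratio(num: int, den: int, empty_vs_empty: bool) -> float:
    if den > 0:
        return num / den
    return 1.0 if empty_vs_empty else 0.0


@dataclass
class SegMetrics:
    iou: float
    dsc: float
    sen: float
    sp: float
    pre: float

    def as_dict(self) -> dict:
        return {"iou": self.iou, "dsc": self.dsc, "sen": self.sen, "sp": self.sp, "pre": self.pre}


def metrics(c: ConfusionCounts) -> SegMetrics:
    """IoU, Dice, sensitivity, specificity and precision from pixel tallies.

    A zero denominator means one side of the comparison is empty; the metric
    is 1 when both sides are empty (empty-vs-empty is a perfect match) and 0
    otherwise.
    """
    both_empty = c.tp + c.fp + c.fn == 0
    iou = _safe_ratio(c.tp, c.tp + c.fp + c.fn, both_empty)
    dsc = _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty)
    sen = _safe_ratio(c.tp, c.tp + c.fn, c.fp == 0)
    sp = _safe_ratio(c.tn, c.tn + c.fp, c.fn == 0)
    pre = _safe_ratio(c.tp, c.tp + c.fp, c.fn == 0)
    return SegMetrics(iou=iou, dsc=dsc, sen=sen, sp=sp, pre=pre)


def write_metrics_csv(path, per_image: list[tuple[str, ConfusionCounts]], macro: bool = False) -> SegMetrics:
    """Write per-image and aggregate metrics; returns the aggregate.

    The aggregate is the micro-average (metrics of the pooled pixel tallies)
    unless ``macro`` is set, in which case per-image metrics are averaged.
    """
    rows = []
    agg = ConfusionCounts(0, 0, 0, 0)
    for name, c in per_image:
        m = metrics(c)
        rows.append({"image": name, **m.as_dict(), "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn})
        agg = agg + c
    if macro and rows:
        mean = {k: float(np.mean([r[k] for r in rows])) for k in ("iou", "dsc", "sen", "sp", "pre")}
        final = SegMetrics(**mean)
    else:
        final = metrics(agg)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["image", "iou", "dsc", "sen", "sp", "pre", "tp", "fp", "tn", "fn"]
        )
        writer.writeheader()
        for r in rows:
            writer.writerow(r)
        writer.writerow(
            {
                "image": "aggregate_macro" if macro else "aggregate_micro",
                **final.as_dict(),
                "tp": agg.tp,
                "fp": agg.fp,
                "tn": agg.tn,
                "fn": agg.fn,
            }
        )
    return final
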