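"""Segmentation metrics (Sen, Spe, Dice, 95HD) and efficiency indicators.

Pixel masks use the row-major, 0-based, pixel-center coordinate convention
throughout.  The ratio metrics are

    Sen  = TP / (TP + FN)
    Spe  = TN / (TN + FP)
    Dice = 2·TP / (FP + 2·TP + FN)

and 95HD is the 95th-percentile Hausdorff distance between the two masks'
foreground point sets: for each directed nearest-neighbor distance multiset
the (linear-interpolated) 95th percentile is taken, and the two directions
are combined by their maximum.  ``percentile=100`` recovers the exact
Hausdorff distance.  Distances are in pixel units.

Undefined values (empty masks, zero denominators) are reported as ``None``
rather than NaN and excluded from dataset means, with exclusion counts kept.

Efficiency indicators: ``count_params`` sums learnable scalars,
``estimate_flops`` counts 2×multiply-accumulates of one forward pass at a
stated input size (hardware-independent), and ``checkpoint_bytes`` measures
the serialized weight size.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .autodiff import Tensor
from . import nn as _nn
from .model import checkpoint_bytes  # re-exported: part of the efficiency surface

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "EfficiencyReport",
    "confusion",
    "ratio_metrics",
    "hd95",
    "evaluate_pair",
    "count_params",
    "estimate_flops",
    "checkpoint_bytes",
    "efficiency_report",
    "write_metrics_csv",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    sen: float | None
    spe: float | None
    dice: float | None
    hd95: float | None
    id: str = ""


@dataclass
class EfficiencyReport:
    params: int
    flops: float
    memory_bytes: int


def _check_mask(m, name: str) -> np.ndarray:
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0,1}}, found values {vals[:10]}")
    return m.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    p = _check_mask(pred, "pred")
    t = _check_mask(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def ratio_metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(Sen, Spe, Dice); a zero denominator yields None for that metric."""
    sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    spe = c.tn / (c.tn + c.fp) if c.tn + c.fp else None
    den = c.fp + 2 * c.tp + c.fn
    dice = 2 * c.tp / den if den else None
    return sen, spe, dice


def hd95(a, b, percentile: float = 95.0) -> float | None:
    """Percentile Hausdorff distance between two masks' foreground pixels."""
    am = _check_mask(a, "A")
    bm = _check_mask(b, "B")
    if am.shape != bm.shape:
        raise ValueError(f"shape mismatch: A {am.shape} vs B {bm.shape}")
    if not am.any() or not bm.any():
        return None
    # exact Euclidean distance-to-set via the distance transform
    dist_to_b = ndimage.distance_transform_edt(~bm)
    dist_to_a = ndimage.distance_transform_edt(~am)
    d_ab = dist_to_b[am]
    d_ba = dist_to_a[bm]
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def evaluate_pair(pred, truth, sample_id: str = "") -> MetricsReport:
    sen, spe, dice = ratio_metrics(confusion(pred, truth))
    return MetricsReport(sen=sen, spe=spe, dice=dice, hd95=hd95(pred, truth), id=sample_id)


# ---- efficiency ------------------------------------------------------------


def count_params(model: _nn.Module) -> int:
    return model.num_params()


def estimate_flops(model: _nn.Module, input_shape: tuple[int, ...]) -> float:
    """Floating-point operation count (2·MACs) of one eval-mode forward."""
    was_training = model.training
    model.eval()
    try:
        with ad.no_grad(), ad.flop_counter() as box:
            model(Tensor(np.zeros(input_shape, dtype=ad.DEFAULT_DTYPE)))
    finally:
        model.train(was_training)
    return box.total


def efficiency_report(model, input_shape: tuple[int, ...]) -> EfficiencyReport:
    return EfficiencyReport(
        params=count_params(model),
        flops=estimate_flops(model, input_shape),
        memory_bytes=checkpoint_bytes(model),
    )


# ---- report I/O ------------------------------------------------------------


def summarize(reports: list[MetricsReport]) -> dict:
    """Means of the defined values per metric, plus undefined counts."""
    out = {}
    for key in ("sen", "spe", "dice", "hd95"):
        vals = [getattr(r, key) for r in reports]
        defined = [v for v in vals if v is not None]
        out[f"mean_{key}"] = float(np.mean(defined)) if defined else None
        out[f"n_undefined_{key}"] = len(vals) - len(defined)
    out["n"] = len(reports)
    return out


def write_metrics_csv(reports: list[MetricsReport], path) -> dict:
    """One row per image plus a summary row of means; returns the summary."""
    summary = summarize(reports)

    def fmt(v):
        return "NA" if v is None else f"{v:.6f}"

    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sen", "spe", "dice", "hd95"])
        for r in reports:
            w.writerow([r.id, fmt(r.sen), fmt(r.spe), fmt(r.dice), fmt(r.hd95)])
        w.writerow(
            ["mean", fmt(summary["mean_sen"]), fmt(summary["mean_spe"]),
             fmt(summary["mean_dice"]), fmt(summary["mean_hd95"])]
        )
    return summary


def write_efficiency_report(report: EfficiencyReport, path) -> None:
    Path(path).write_text(
        f"params: {report.params}\n"
        f"flops: {report.flops:.0f}\n"
        f"memory_bytes: {report.memory_bytes}\n"
    )
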