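"""Joint deep-supervision loss: weighted BCE + soft-Dice per scale.

The total loss is ``L = Σ_i λ_i · (BCE(y_i, p_i) + k · DiceLoss(y_i, p_i))``
where ``p_i`` is the softmax foreground probability at supervision level i,
``y_i`` the ground-truth mask downsampled (nearest-neighbor) to that level,
``λ_i`` the per-level weights (normalized to sum to 1) and ``k`` the Dice
weight.  BCE is the per-pixel mean binary cross-entropy of the foreground
probability; the Dice loss is ``1 − (2Σpy + s)/(Σp + Σy + s)`` with
smoothing ``s``, the soft counterpart of ``Dice = 2TP/(FP + 2TP + FN)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import SegmentationOutput

_P_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    level_weights: tuple[float, ...] = (1.0, 0.5, 0.25)
    dice_weight: float = 1.0
    smooth: float = 1e-5

    def __post_init__(self):
        lw = np.asarray(self.level_weights, dtype=float)
        if (lw < 0).any() or lw.sum() <= 0:
            raise ValueError("level weights must be non-negative with positive sum")
        if self.dice_weight <= 0:
            raise ValueError("dice_weight must be positive")
        object.__setattr__(self, "level_weights", tuple(lw / lw.sum()))


def _check_binary(target: np.ndarray) -> np.ndarray:
    target = np.asarray(target)
    vals = np.unique(target)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"target must be binary {{0,1}}, found values {vals[:10]}")
    return target.astype(np.float64)


def bce_dice_level_loss(pred_probs: Tensor, target: np.ndarray, cfg: LossConfig) -> Tensor:
    """Single-level loss: mean foreground BCE + k·(1 − soft Dice).

    ``pred_probs``: (b, num_classes, h, w) class probabilities (rows sum to 1
    over the class axis); ``target``: (b, h, w) binary mask.
    """
    t = _check_binary(target)
    if pred_probs.shape[0] != t.shape[0] or pred_probs.shape[2:] != t.shape[1:]:
        raise ValueError(
            f"prediction {pred_probs.shape} incompatible with target {t.shape}"
        )
    p_fg = ad.narrow(pred_probs, 1, pred_probs.shape[1] - 1, 1)
    p_fg = ad.reshape(p_fg, t.shape)
    p = ad.clip(p_fg, _P_EPS, 1.0 - _P_EPS)
    tt = Tensor(t.astype(pred_probs.dtype))
    bce = -(tt * ad.log(p) + (1.0 - tt) * ad.log(1.0 - p)).mean()
    s = cfg.smooth
    inter = (p_fg * tt).sum()
    dice = (2.0 * inter + s) / (p_fg.sum() + tt.sum() + s)
    return bce + cfg.dice_weight * (1.0 - dice)


def downsample_mask(target: np.ndarray, level: int) -> np.ndarray:
    """Nearest-neighbor ×2^level downsampling (preserves binarity)."""
    f = 2**level
    return np.asarray(target)[:, ::f, ::f]


def deep_supervision_loss(
    output: SegmentationOutput, target: np.ndarray, cfg: LossConfig
) -> Tensor:
    """Eq.-style weighted sum of per-level BCE+Dice losses, finest first."""
    logits = output.logits if isinstance(output, SegmentationOutput) else list(output)
    if len(logits) != len(cfg.level_weights):
        raise ValueError(
            f"{len(logits)} supervision levels but {len(cfg.level_weights)} weights"
        )
    total = None
    for i, (lam, lg) in enumerate(zip(cfg.level_weights, logits)):
        if lam == 0.0:
            continue
        probs = ad.softmax(lg, axis=1)
        term = lam * bce_dice_level_loss(probs, downsample_mask(target, i), cfg)
        total = term if total is None else total + term
    return total
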