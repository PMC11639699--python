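"""Training, evaluation and prediction workflows.

The training protocol mirrors the usual nnU-Net-style recipe: SGD with
Nesterov momentum 0.99, polynomial learning-rate decay
``lr · (1 − step/total)^0.9``, decoupled L2 weight decay, deep-supervision
BCE+Dice loss, and forced-foreground sampling — each batch slot draws a
lesion-containing image with probability ``fg_sample_ratio`` and a
background-only image otherwise (falling back to the whole pool when one
side is empty), which counters class imbalance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .losses import LossConfig, deep_supervision_loss
from .metrics import MetricsReport, evaluate_pair, summarize
from .model import NTSM, NTSMConfig, build_ntsm, save_checkpoint
from .synthetic import ImageSample


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    weight_decay: float = 0.00003
    batch_size: int = 4
    iters_per_epoch: int = 250
    epochs: int = 300
    fg_sample_ratio: float = 0.33
    fold: int = 0
    seed: int = 0
    momentum: float = 0.99
    nesterov: bool = True
    poly_power: float = 0.9

    def __post_init__(self):
        if not 0 < self.fg_sample_ratio <= 1:
            raise ValueError("fg_sample_ratio must lie in (0, 1]")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch statistics degenerate at 1)")


class ForegroundBalancedSampler:
    """Per-slot Bernoulli(fg_ratio) choice between lesion and background pools."""

    def __init__(self, samples: list[ImageSample], fg_ratio: float, rng: np.random.Generator):
        self.rng = rng
        self.fg_ratio = fg_ratio
        self.fg_idx = [i for i, s in enumerate(samples) if s.mask.any()]
        self.bg_idx = [i for i, s in enumerate(samples) if not s.mask.any()]
        self.all_idx = list(range(len(samples)))
        if not self.all_idx:
            raise ValueError("empty sample list")

    def draw(self, batch_size: int) -> list[int]:
        out = []
        for _ in range(batch_size):
            want_fg = self.rng.random() < self.fg_ratio
            pool = self.fg_idx if want_fg else self.bg_idx
            if not pool:
                pool = self.all_idx
            out.append(pool[self.rng.integers(len(pool))])
        return out


def _to_batch(samples: list[ImageSample], idx: list[int]) -> tuple[Tensor, np.ndarray]:
    images = np.stack([samples[i].image for i in idx]).astype(ad.DEFAULT_DTYPE) / 255.0
    masks = np.stack([samples[i].mask for i in idx]).astype(np.uint8)
    return Tensor(images.transpose(0, 3, 1, 2)), masks


def fit(
    model: NTSM,
    samples: list[ImageSample],
    train_cfg: TrainConfig,
    total_steps: int,
    loss_cfg: LossConfig | None = None,
    log_every: int = 0,
) -> list[float]:
    """Run ``total_steps`` optimization steps; returns the loss trajectory."""
    if loss_cfg is None:
        loss_cfg = LossConfig(
            level_weights=tuple(0.5**i for i in range(model.config.deep_supervision_levels))
        )
    rng = np.random.default_rng(train_cfg.seed)
    sampler = ForegroundBalancedSampler(samples, train_cfg.fg_sample_ratio, rng)
    opt = nn.SGD(
        model.parameters(),
        lr=train_cfg.lr,
        momentum=train_cfg.momentum,
        nesterov=train_cfg.nesterov,
        weight_decay=train_cfg.weight_decay,
    )
    model.train()
    losses = []
    for step in range(total_steps):
        opt.lr = train_cfg.lr * (1.0 - step / total_steps) ** train_cfg.poly_power
        x, y = _to_batch(samples, sampler.draw(train_cfg.batch_size))
        loss = deep_supervision_loss(model(x), y, loss_cfg)
        val = loss.item()
        if not np.isfinite(val):
            raise RuntimeError(
                f"training diverged at step {step}: loss = {val}; lower the learning rate"
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(val)
        if log_every and step % log_every == 0:
            print(f"step {step:5d}  lr {opt.lr:.5f}  loss {val:.4f}")
    return losses


def evaluate_model(model: NTSM, samples: list[ImageSample]) -> list[MetricsReport]:
    """Per-image Sen/Spe/Dice/95HD of argmax predictions."""
    reports = []
    for s in samples:
        x = Tensor(s.image.transpose(2, 0, 1)[None].astype(ad.DEFAULT_DTYPE) / 255.0)
        pred = model.predict_mask(x)[0]
        reports.append(evaluate_pair(pred, s.mask, sample_id=s.id))
    return reports


def predict_masks(model: NTSM, images: list[np.ndarray]) -> list[np.ndarray]:
    return [
        model.predict_mask(Tensor(im.transpose(2, 0, 1)[None].astype(ad.DEFAULT_DTYPE) / 255.0))[0]
        for im in images
    ]


def train(
    samples: list[ImageSample],
    fold_assignments: dict,
    model_cfg: NTSMConfig,
    train_cfg: TrainConfig,
    out_dir,
    loss_cfg: LossConfig | None = None,
) -> tuple[NTSM, list[dict]]:
    """Cross-validation training: fit on 4 folds, validate on the held-out one.

    Writes a CSV log (epoch, train_loss, val_loss, val_dice) and saves the
    best-validation-Dice checkpoint under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.id: s for s in samples}
    train_ids = [i for i, f in sorted(fold_assignments.items()) if f != train_cfg.fold]
    val_ids = [i for i, f in sorted(fold_assignments.items()) if f == train_cfg.fold]
    if not train_ids or not val_ids:
        raise ValueError(f"fold {train_cfg.fold} leaves an empty train or validation set")
    train_set = [by_id[i] for i in train_ids]
    val_set = [by_id[i] for i in val_ids]

    model = build_ntsm(model_cfg)
    if loss_cfg is None:
        loss_cfg = LossConfig(
            level_weights=tuple(0.5**i for i in range(model_cfg.deep_supervision_levels))
        )
    rng = np.random.default_rng(train_cfg.seed)
    sampler = ForegroundBalancedSampler(train_set, train_cfg.fg_sample_ratio, rng)
    opt = nn.SGD(
        model.parameters(),
        lr=train_cfg.lr,
        momentum=train_cfg.momentum,
        nesterov=train_cfg.nesterov,
        weight_decay=train_cfg.weight_decay,
    )
    total_steps = train_cfg.epochs * train_cfg.iters_per_epoch
    log: list[dict] = []
    best_dice = -1.0
    step = 0
    ckpt = out_dir / "checkpoint_best.npz"
    for epoch in range(train_cfg.epochs):
        model.train()
        epoch_losses = []
        for _ in range(train_cfg.iters_per_epoch):
            opt.lr = train_cfg.lr * (1.0 - step / total_steps) ** train_cfg.poly_power
            x, y = _to_batch(train_set, sampler.draw(train_cfg.batch_size))
            loss = deep_supervision_loss(model(x), y, loss_cfg)
            val = loss.item()
            if not np.isfinite(val):
                raise RuntimeError(f"training diverged at epoch {epoch}, loss = {val}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(val)
            step += 1
        model.eval()
        val_losses = []
        with ad.no_grad():
            for s in val_set:
                x, y = _to_batch([s], [0])
                val_losses.append(deep_supervision_loss(model(x), y, loss_cfg).item())
        val_dice = summarize(evaluate_model(model, val_set))["mean_dice"]
        val_dice = -0.0 if val_dice is None else val_dice
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": float(np.mean(val_losses)),
            "val_dice": float(val_dice),
        }
        log.append(row)
        if val_dice > best_dice:
            best_dice = val_dice
            save_checkpoint(model, ckpt)
    with (out_dir / "training_log.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss", "val_dice"])
        writer.writeheader()
        writer.writerows(log)
    return model, log
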