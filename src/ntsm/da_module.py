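"""Difference-association (DA) module: LCD and LSA submodules.

The DA module sits at the input of the segmentation network and amplifies the
feature differences between non-salient lesions and their surroundings.

* LCD (local context difference) runs two low-level comparison extractor
  (LCE) units.  Each unit computes a *local* branch (3×3 convolution,
  dilation 1, followed by LFE gating) and a *context* branch (3×3
  convolution with a larger dilation — 4 for the first unit, 8 for the
  second — followed by LFE), then takes the contrast
  ``LeakyReLU(InstanceNorm(local − context))``.  The two contrast maps are
  fused (channel concatenation + 1×1 convolution by default) into F_c.
* LSA (logical semantic association) disambiguates true lesions from
  high-contrast distractors by fusing four convolutional branches with
  progressively larger receptive fields (1×1; 1×1→7×7→3×3 dilated 7;
  twice 1×1→7×7→7×7→3×3 dilated 7), plus a 1×1 shortcut from its input,
  producing F_s with the same shape as F_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .attention_primitives import LFE


@dataclass(frozen=True)
class DAConfig:
    """Dilations, widths and activation slope of the DA module."""

    lcd_context_dilations: tuple[int, int] = (4, 8)
    lcd_local_dilation: int = 1
    lsa_final_dilation: int = 7
    out_channels: int = 32
    negative_slope: float = 0.01
    lce_fusion: str = "concat"  # "concat" (1×1-reduced) or "sum"

    def __post_init__(self):
        if any(d < 1 for d in self.lcd_context_dilations) or self.lcd_local_dilation < 1:
            raise ValueError("dilations must be >= 1")
        if self.lsa_final_dilation < 1:
            raise ValueError("dilations must be >= 1")
        if self.out_channels < 4:
            raise ValueError("out_channels must be >= 4")
        if self.lce_fusion not in ("concat", "sum"):
            raise ValueError(f"unknown lce_fusion {self.lce_fusion!r}")


def lce_contrast(
    f_local: Tensor, f_context: Tensor, negative_slope: float = 0.01, eps: float = 1e-5
) -> Tensor:
    """Low-level comparison extractor: LeakyReLU(InstanceNorm(local − context)).

    Instance normalization (per batch-channel slice, no affine terms) removes
    each slice's mean, so a spatially constant difference maps to zero.
    """
    if f_local.shape != f_context.shape:
        raise ValueError(
            f"lce_contrast shape mismatch: local {f_local.shape} vs context {f_context.shape}"
        )
    diff = f_local - f_context
    mu = diff.mean(axis=(2, 3), keepdims=True)
    centered = diff - mu
    var = (centered * centered).mean(axis=(2, 3), keepdims=True)
    return ad.leaky_relu(centered * ad.pow_const(var + eps, -0.5), negative_slope)


class _LCEUnit(nn.Module):
    """One LCE unit: local and context receptor branches, each conv → LFE."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        local_dilation: int,
        context_dilation: int,
        negative_slope: float,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.negative_slope = negative_slope
        self.local_conv = nn.Conv2d(
            in_channels, out_channels, 3, rng, padding=local_dilation, dilation=local_dilation
        )
        self.local_lfe = LFE(out_channels, rng)
        self.context_conv = nn.Conv2d(
            in_channels, out_channels, 3, rng, padding=context_dilation, dilation=context_dilation
        )
        self.context_lfe = LFE(out_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        f_local = self.local_lfe(self.local_conv(x))
        f_context = self.context_lfe(self.context_conv(x))
        return lce_contrast(f_local, f_context, self.negative_slope)


class LCD(nn.Module):
    """Local context difference submodule (two LCE units, fused)."""

    def __init__(self, in_channels: int, cfg: DAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d_ctx_a, d_ctx_b = cfg.lcd_context_dilations
        self.unit_a = _LCEUnit(
            in_channels, cfg.out_channels, cfg.lcd_local_dilation, d_ctx_a, cfg.negative_slope, rng
        )
        self.unit_b = _LCEUnit(
            in_channels, cfg.out_channels, cfg.lcd_local_dilation, d_ctx_b, cfg.negative_slope, rng
        )
        if cfg.lce_fusion == "concat":
            self.fuse = nn.Conv2d(2 * cfg.out_channels, cfg.out_channels, 1, rng)
        else:
            self.fuse = None

    def forward(self, x: Tensor) -> Tensor:
        ca = self.unit_a(x)
        cb = self.unit_b(x)
        if self.fuse is not None:
            return self.fuse(ad.concat([ca, cb], axis=1))
        return ca + cb


class LSA(nn.Module):
    """Logical semantic association submodule (four dilated branches + shortcut)."""

    def __init__(self, cfg: DAConfig, rng: np.random.Generator):
        super().__init__()
        C = cfg.out_channels
        d = cfg.lsa_final_dilation
        self.channels = C
        self.negative_slope = cfg.negative_slope
        # branch 1: 1×1 conv + BN
        self.b1 = nn.Sequential(nn.Conv2d(C, C, 1, rng), nn.BatchNorm2d(C))
        # branch 2: 1×1 → 7×7 → 3×3 (dilation d); BN after every conv, GeLU after all but the last
        self.b2 = nn.Sequential(
            nn.Conv2d(C, C, 1, rng), nn.BatchNorm2d(C), nn.GELU(),
            nn.Conv2d(C, C, 7, rng, padding=3), nn.BatchNorm2d(C), nn.GELU(),
            nn.Conv2d(C, C, 3, rng, padding=d, dilation=d), nn.BatchNorm2d(C),
        )
        # branches 3, 4: same topology (1×1 → 7×7 → 7×7 → 3×3 dilated), independent weights
        def deep_branch():
            return nn.Sequential(
                nn.Conv2d(C, C, 1, rng), nn.BatchNorm2d(C), nn.GELU(),
                nn.Conv2d(C, C, 7, rng, padding=3), nn.BatchNorm2d(C), nn.GELU(),
                nn.Conv2d(C, C, 7, rng, padding=3), nn.BatchNorm2d(C), nn.GELU(),
                nn.Conv2d(C, C, 3, rng, padding=d, dilation=d), nn.BatchNorm2d(C),
            )

        self.b3 = deep_branch()
        self.b4 = deep_branch()
        self.fuse = nn.Sequential(
            nn.Conv2d(4 * C, C, 3, rng, padding=d, dilation=d), nn.BatchNorm2d(C)
        )
        self.shortcut = nn.Sequential(nn.Conv2d(C, C, 1, rng), nn.BatchNorm2d(C))

    def forward(self, f_c: Tensor) -> Tensor:
        if f_c.shape[1] != self.channels:
            raise ValueError(f"LSA built for {self.channels} channels, got {f_c.shape[1]}")
        f_t = ad.concat([self.b1(f_c), self.b2(f_c), self.b3(f_c), self.b4(f_c)], axis=1)
        return ad.leaky_relu(self.fuse(f_t) + self.shortcut(f_c), self.negative_slope)


class DAModule(nn.Module):
    """Full difference-association module: LCD followed by LSA."""

    def __init__(self, in_channels: int, cfg: DAConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.lcd = LCD(in_channels, cfg, rng)
        self.lsa = LSA(cfg, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.lsa(self.lcd(x))


def lcd_forward(x: Tensor, lcd: LCD) -> Tensor:
    return lcd(x)


def lsa_forward(f_c: Tensor, lsa: LSA) -> Tensor:
    return lsa(f_c)
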