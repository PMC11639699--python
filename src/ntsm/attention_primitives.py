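"""Reusable attention operators: the low-level feature extractor (LFE) and
Hadamard-product attention (HPA).

LFE is a dual 1-D pooled gating attention in the coordinate-attention style:
the input is average-pooled along each spatial axis separately, the two
pooled strips are jointly embedded through a shared 1×1 bottleneck
(batch norm + swish), then split again and turned into per-axis sigmoid
gates that multiplicatively re-weight the input.  Because both gates lie in
(0, 1), the output magnitude never exceeds the input's.

HPA multiplies its input elementwise by a gate derived from a small learnable
tensor ``p``: ``p`` is stored on a fixed nominal grid, bilinearly resized to
the input's trailing spatial extents at every forward call, sharpened by a
per-slice 3×3 depthwise convolution, and applied as a Hadamard product.  The
gate depends only on ``p``, so HPA is exactly linear in its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import nn


@dataclass(frozen=True)
class HPAParams:
    """Configuration of the learnable HPA tensor ``p``.

    nominal_grid : stored spatial extent of ``p`` (resized per forward call);
        both extents must be >= 2 so bilinear interpolation is well posed.
    init_std : standard deviation of the truncated-normal initialization.
    """

    nominal_grid: tuple[int, int] = (16, 16)
    init_std: float = 0.02

    def __post_init__(self):
        g1, g2 = self.nominal_grid
        if g1 < 2 or g2 < 2:
            raise ValueError(f"nominal_grid extents must be >= 2, got {self.nominal_grid}")
        if self.init_std <= 0:
            raise ValueError("init_std must be positive")


class LFE(nn.Module):
    """Low-level feature extractor: dual 1-D pooled gating attention.

    Parameters
    ----------
    channels : input/output channel count C.
    reduction : bottleneck ratio; the shared embedding has
        ``max(C // reduction, min_mid)`` channels.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 8, min_mid: int = 4):
        super().__init__()
        self.channels = channels
        mid = max(channels // reduction, min_mid)
        self.conv_mid = nn.Conv2d(channels, mid, 1, rng)
        self.bn = nn.BatchNorm2d(mid)
        self.gate_h = nn.Conv2d(mid, channels, 1, rng)
        self.gate_w = nn.Conv2d(mid, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError(f"LFE expects a (b, C, h, w) tensor, got shape {x.shape}")
        b, C, h, w = x.shape
        if h < 1 or w < 1:
            raise ValueError(f"spatial extents must be >= 1, got {(h, w)}")
        if C != self.channels:
            raise ValueError(f"LFE built for {self.channels} channels, got {C}")
        pool_h = x.mean(axis=3, keepdims=True)                    # (b, C, h, 1)
        pool_w = x.mean(axis=2, keepdims=True)                    # (b, C, 1, w)
        pool_w_t = ad.permute(pool_w, (0, 1, 3, 2))               # (b, C, w, 1)
        mid = ad.concat([pool_h, pool_w_t], axis=2)               # (b, C, h+w, 1)
        mid = ad.swish(self.bn(self.conv_mid(mid)))
        mid_h = ad.narrow(mid, 2, 0, h)                           # (b, mid, h, 1)
        mid_w = ad.permute(ad.narrow(mid, 2, h, w), (0, 1, 3, 2))  # (b, mid, 1, w)
        g_h = ad.sigmoid(self.gate_h(mid_h))                      # (b, C, h, 1)
        g_w = ad.sigmoid(self.gate_w(mid_w))                      # (b, C, 1, w)
        return x * g_h * g_w


class HPA(nn.Module):
    """Hadamard-product attention over the trailing two axes.

    ``depth`` is the extent of the gate's leading axis: the learnable tensor
    ``p`` has shape (depth, *nominal_grid) and the depthwise convolution has
    one 3×3 filter per leading slice.  The resulting gate broadcasts against
    the input's leading axes, so the same module serves the height-width axis
    (depth = channels) and the channel-height / channel-width axes
    (depth = 1, gate shared across the folded-out spatial axis).
    """

    def __init__(self, depth: int, params: HPAParams, rng: np.random.Generator):
        super().__init__()
        self.depth = depth
        self.params = params
        g1, g2 = params.nominal_grid
        self.p = nn.Parameter(nn.trunc_normal((depth, g1, g2), params.init_std, rng))
        self.dw_weight = nn.Parameter(nn.he_normal((depth, 1, 3, 3), 9, rng))
        self.dw_bias = nn.Parameter(np.zeros(depth))

    def gate(self, size: tuple[int, int]) -> Tensor:
        """The batch-independent gate at the given trailing extents."""
        if size[0] < 1 or size[1] < 1:
            raise ValueError(f"gate target extent must be >= 1, got {size}")
        resized = ad.bilinear_resize(self.p, size)                # (D, A1, A2)
        g = ad.conv2d(
            ad.reshape(resized, (1, self.depth) + tuple(size)),
            self.dw_weight,
            self.dw_bias,
            padding=1,
            groups=self.depth,
        )
        return ad.reshape(g, (self.depth,) + tuple(size))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim < 3:
            raise ValueError(f"HPA needs >= 2 trailing attended axes plus a leading slice axis, got shape {x.shape}")
        return x * self.gate((x.shape[-2], x.shape[-1]))


def lfe_forward(x: Tensor, lfe: LFE) -> Tensor:
    """Functional wrapper around :class:`LFE`."""
    return lfe(x)


def hpa_forward(x: Tensor, hpa: HPA) -> Tensor:
    """Functional wrapper around :class:`HPA`."""
    return hpa(x)
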