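"""Neural-network layers and an SGD optimizer on top of :mod:`ntsm.autodiff`.

Follows the familiar Module/Parameter pattern: layers register parameters and
sub-modules by attribute assignment, expose ``state_dict``/``load_state_dict``
for checkpointing, and a ``training`` flag that switches normalization layers
between batch and running statistics.

All random initialization draws from an explicitly passed
``numpy.random.Generator`` so that two builds with the same seed are
parameter-for-parameter identical.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x",
    "BatchNorm2d",
    "InstanceNorm2d",
    "GroupNorm",
    "LeakyReLU",
    "GELU",
    "Swish",
    "Identity",
    "SGD",
    "trunc_normal",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=ad.DEFAULT_DTYPE), requires_grad=True)


def trunc_normal(shape, std: float, rng: np.random.Generator) -> np.ndarray:
    """Normal(0, std) truncated at ±2 std, drawn from ``rng``."""
    return truncnorm.rvs(-2.0, 2.0, loc=0.0, scale=std, size=shape, random_state=rng)


def he_normal(shape, fan_in: int, rng: np.random.Generator, slope: float = 0.01) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + slope**2))
    return rng.normal(0.0, gain / np.sqrt(fan_in), size=shape)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # ---- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # ---- state ---------------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, b in self.named_buffers():
            out[name] = b.copy()
        return out

    def load_state_dict(self, sd: dict, strict: bool = True) -> None:
        own_p = dict(self.named_parameters())
        own_b = {}
        for name, _ in self.named_buffers():
            own_b[name] = name
        missing = [k for k in list(own_p) + list(own_b) if k not in sd]
        if strict and missing:
            raise KeyError(f"missing state entries: {missing}")
        for name, p in own_p.items():
            if name in sd:
                val = np.asarray(sd[name])
                if val.shape != p.data.shape:
                    raise ValueError(f"shape mismatch for {name}: {val.shape} vs {p.data.shape}")
                p.data = val.astype(p.data.dtype, copy=True)
        # buffers are owned by the holding module; walk modules to assign
        self._load_buffers(sd, "")

    def _load_buffers(self, sd: dict, prefix: str) -> None:
        for name in list(self._buffers):
            key = prefix + name
            if key in sd:
                self._buffers[name] = np.asarray(sd[key]).astype(
                    self._buffers[name].dtype, copy=True
                )
        for name, m in self._modules.items():
            m._load_buffers(sd, prefix + name + ".")

    # ---- mode ----------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def num_params(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def astype(self, dtype):
        """Cast all parameters and buffers (e.g. float64 for precision checks)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for name in list(m._buffers):
                m._buffers[name] = m._buffers[name].astype(dtype)
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        rng: np.random.Generator,
        stride=1,
        padding=0,
        dilation=1,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if in_channels % groups:
            raise ValueError(f"in_channels {in_channels} not divisible by groups {groups}")
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_channels // groups) * kh * kw
        self.weight = Parameter(he_normal((out_channels, in_channels // groups, kh, kw), fan_in, rng))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ad.conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
        )


class ConvTranspose2x(Module):
    """Kernel-2 stride-2 transposed convolution (exact ×2 upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(he_normal((in_channels, out_channels, 2, 2), in_channels * 4, rng))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ad.conv_transpose2x(x, self.weight, self.bias)


def _norm(x: Tensor, axes: tuple, eps: float) -> Tensor:
    mu = ad.tmean(x, axis=axes, keepdims=True)
    centered = x - mu
    var = ad.tmean(centered * centered, axis=axes, keepdims=True)
    return centered * ad.pow_const(var + eps, -0.5)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, affine: bool = True):
        super().__init__()
        self.channels, self.eps, self.momentum, self.affine = channels, eps, momentum, affine
        if affine:
            self.weight = Parameter(np.ones(channels))
            self.bias = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels, dtype=ad.DEFAULT_DTYPE)
        self._buffers["running_var"] = np.ones(channels, dtype=ad.DEFAULT_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            rdt = self._buffers["running_mean"].dtype
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu
            ).astype(rdt)
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var
            ).astype(rdt)
            xhat = _norm(x, (0, 2, 3), self.eps)
        else:
            mu = self._buffers["running_mean"].reshape(1, -1, 1, 1)
            var = self._buffers["running_var"].reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / np.sqrt(var + self.eps))
        if self.affine:
            C = self.channels
            xhat = xhat * ad.reshape(self.weight, (1, C, 1, 1)) + ad.reshape(self.bias, (1, C, 1, 1))
        return xhat


class InstanceNorm2d(Module):
    """Per-(sample, channel) spatial normalization; no running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = False):
        super().__init__()
        self.channels, self.eps, self.affine = channels, eps, affine
        if affine:
            self.weight = Parameter(np.ones(channels))
            self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        xhat = _norm(x, (2, 3), self.eps)
        if self.affine:
            C = self.channels
            xhat = xhat * ad.reshape(self.weight, (1, C, 1, 1)) + ad.reshape(self.bias, (1, C, 1, 1))
        return xhat


class GroupNorm(Module):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by gn groups {groups}")
        self.groups, self.channels, self.eps, self.affine = groups, channels, eps, affine
        if affine:
            self.weight = Parameter(np.ones(channels))
            self.bias = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.groups
        xg = ad.reshape(x, (B, g, C // g, H, W))
        xhat = ad.reshape(_norm(xg, (2, 3, 4), self.eps), (B, C, H, W))
        if self.affine:
            xhat = xhat * ad.reshape(self.weight, (1, C, 1, 1)) + ad.reshape(self.bias, (1, C, 1, 1))
        return xhat


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x):
        return ad.leaky_relu(x, self.negative_slope)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


class Swish(Module):
    def forward(self, x):
        return ad.swish(x)


class SGD:
    """SGD with (optionally Nesterov) momentum and decoupled L2 weight decay."""

    def __init__(
        self,
        params,
        lr: float,
        momentum: float = 0.99,
        nesterov: bool = True,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        m = self.momentum
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= m
            v += g
            update = g + m * v if self.nesterov else v
            p.data = p.data - self.lr * update
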