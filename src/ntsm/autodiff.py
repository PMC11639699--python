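"""Compact reverse-mode automatic differentiation on numpy arrays.

The whole segmentation stack runs on this module: a :class:`Tensor` wraps a
numpy array and records the operations applied to it; :meth:`Tensor.backward`
replays them in reverse topological order to accumulate gradients.  Only the
operations the segmentation modules need are implemented (elementwise
arithmetic, activations, reductions, 2-D convolution with dilation/groups,
2×2 transposed convolution, bilinear resizing, concatenation/slicing).

A lightweight FLOP counter rides along: inside a :func:`flop_counter` context
every forward operation adds ``2 × multiply-accumulates`` (or one op per
element for pure elementwise work) to the active counter, which is how the
efficiency report measures a model's floating-point cost.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import special as _sp

__all__ = [
    "Tensor",
    "no_grad",
    "flop_counter",
    "concat",
    "narrow",
    "permute",
    "reshape",
    "conv2d",
    "conv_transpose2x",
    "bilinear_resize",
    "softmax",
    "sigmoid",
    "swish",
    "gelu",
    "leaky_relu",
    "erf",
    "exp",
    "log",
    "clip",
]

_grad_enabled = True
_flop_boxes: list["FlopCounter"] = []

#: dtype used for parameters and non-float inputs; float32 keeps the im2col
#: working arrays small enough for fast CPU training, while individual
#: modules can be cast to float64 (``Module.astype``) for high-precision checks.
DEFAULT_DTYPE = np.float32

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


_einsum_paths: dict = {}


def _einsum(subscripts: str, *ops: np.ndarray) -> np.ndarray:
    """np.einsum with the contraction path cached per (signature, shapes)."""
    key = (subscripts, tuple(op.shape for op in ops))
    path = _einsum_paths.get(key)
    if path is None:
        path, _ = np.einsum_path(subscripts, *ops, optimize="optimal")
        _einsum_paths[key] = path
    return np.einsum(subscripts, *ops, optimize=path)


class FlopCounter:
    """Accumulates an operation count during forward passes."""

    def __init__(self) -> None:
        self.total = 0.0


@contextmanager
def no_grad():
    """Disable graph construction (evaluation / inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


@contextmanager
def flop_counter():
    box = FlopCounter()
    _flop_boxes.append(box)
    try:
        yield box
    finally:
        _flop_boxes.remove(box)


def _flops(n: float) -> None:
    if _flop_boxes:
        for box in _flop_boxes:
            box.total += n


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(DEFAULT_DTYPE)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._bwd = None

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- autograd ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # ---- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul_const(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul_const(self, 1.0 / other)
        return mul(self, pow_const(other, -1.0))

    def __rtruediv__(self, other):
        return mul_const(pow_const(self, -1.0), float(other))

    def __pow__(self, c):
        return pow_const(self, float(c))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents, bwd) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._bwd = bwd
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---- elementwise binary ops ------------------------------------------------


def add(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        return add_const(_wrap(a), float(b))
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data
    _flops(out.size)

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _node(out, (a, b), bwd)


def add_const(a: Tensor, c: float) -> Tensor:
    out = a.data + c
    _flops(out.size)

    def bwd(g):
        _accum(a, g)

    return _node(out, (a,), bwd)


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        return mul_const(_wrap(a), float(b))
    a, b = _wrap(a), _wrap(b)
    out = a.data * b.data
    _flops(out.size)

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), bwd)


def mul_const(a: Tensor, c: float) -> Tensor:
    out = a.data * c
    _flops(out.size)

    def bwd(g):
        _accum(a, g * c)

    return _node(out, (a,), bwd)


def pow_const(a: Tensor, c: float) -> Tensor:
    out = a.data**c
    _flops(out.size)

    def bwd(g):
        _accum(a, g * (c * a.data ** (c - 1.0)))

    return _node(out, (a,), bwd)


# ---- elementwise unary ops -------------------------------------------------


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    _flops(a.size)

    def bwd(g):
        _accum(a, g * out)

    return _node(out, (a,), bwd)


def log(a: Tensor) -> Tensor:
    out = np.log(a.data)
    _flops(a.size)

    def bwd(g):
        _accum(a, g / a.data)

    return _node(out, (a,), bwd)


def sigmoid(a: Tensor) -> Tensor:
    out = _sp.expit(a.data)
    _flops(2 * a.size)

    def bwd(g):
        _accum(a, g * out * (1.0 - out))

    return _node(out, (a,), bwd)


def swish(a: Tensor) -> Tensor:
    """x * sigmoid(x)."""
    s = _sp.expit(a.data)
    out = a.data * s
    _flops(3 * a.size)

    def bwd(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _node(out, (a,), bwd)


def erf(a: Tensor) -> Tensor:
    out = _sp.erf(a.data)
    _flops(2 * a.size)

    def bwd(g):
        _accum(a, g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data * a.data))

    return _node(out, (a,), bwd)


def gelu(a: Tensor) -> Tensor:
    """Exact Gaussian-CDF GeLU: x * Phi(x)."""
    phi = 0.5 * (1.0 + _sp.erf(a.data * _INV_SQRT2))
    out = a.data * phi
    _flops(4 * a.size)

    def bwd(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * a.data * a.data)
        _accum(a, g * (phi + a.data * pdf))

    return _node(out, (a,), bwd)


def leaky_relu(a: Tensor, negative_slope: float = 0.01) -> Tensor:
    out = np.where(a.data >= 0, a.data, a.data * negative_slope)
    _flops(a.size)

    def bwd(g):
        _accum(a, np.where(a.data >= 0, g, g * negative_slope))

    return _node(out, (a,), bwd)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    out = np.clip(a.data, lo, hi)

    def bwd(g):
        _accum(a, np.where((a.data > lo) & (a.data < hi), g, 0.0))

    return _node(out, (a,), bwd)


# ---- shape ops -------------------------------------------------------------


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    out = a.data.reshape(shape)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(out, (a,), bwd)


def permute(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = a.data.transpose(axes)

    def bwd(g):
        _accum(a, g.transpose(inv))

    return _node(out, (a,), bwd)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _node(out, tuple(tensors), bwd)


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    out = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    return _node(out, (a,), bwd)


def chunk(a: Tensor, n: int, axis: int) -> list[Tensor]:
    extent = a.shape[axis]
    if extent % n:
        raise ValueError(f"axis extent {extent} not divisible into {n} chunks")
    step = extent // n
    return [narrow(a, axis, i * step, step) for i in range(n)]


# ---- reductions ------------------------------------------------------------


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)
    _flops(a.size)

    def bwd(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(i % a.ndim for i in ax)
            gg = np.expand_dims(gg, ax)
        _accum(a, np.broadcast_to(gg, a.data.shape))

    return _node(out, (a,), bwd)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return mul_const(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a: Tensor, axis: int) -> Tensor:
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return mul(e, pow_const(tsum(e, axis=axis, keepdims=True), -1.0))


# ---- convolution -----------------------------------------------------------


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride=1,
    padding=0,
    dilation=1,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation with zero padding, dilation and channel groups.

    ``x``: (B, C, H, W); ``w``: (O, C/groups, kh, kw); ``b``: (O,) or None.
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    xd, wd = x.data, w.data
    if xd.ndim != 4:
        raise ValueError(f"conv2d expects rank-4 input, got shape {xd.shape}")
    B, C, H, W = xd.shape
    O, Cg, kh, kw = wd.shape
    g = groups
    if C != Cg * g or O % g:
        raise ValueError(
            f"channel mismatch: input {C} channels, weight {wd.shape}, groups {g}"
        )
    Og = O // g
    if ph or pw:
        xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = xd
    Hp, Wp = xp.shape[2:]
    oh = (Hp - (kh - 1) * dh - 1) // sh + 1
    ow = (Wp - (kw - 1) * dw - 1) // sw + 1
    if oh < 1 or ow < 1:
        raise ValueError(f"conv2d output extent < 1 for input {xd.shape}")
    xg = xp.reshape(B, g, Cg, Hp, Wp)
    s = xg.strides
    cols = as_strided(
        xg,
        shape=(B, g, Cg, kh, kw, oh, ow),
        strides=(s[0], s[1], s[2], s[3] * dh, s[4] * dw, s[3] * sh, s[4] * sw),
    )
    wg = wd.reshape(g, Og, Cg, kh, kw)
    out = _einsum("bgcijuv,gocij->bgouv", cols, wg)
    out = out.reshape(B, O, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)
    _flops(2.0 * B * O * Cg * kh * kw * oh * ow + (B * O * oh * ow if b is not None else 0))

    parents = (x, w) if b is None else (x, w, b)

    def bwd(gout):
        go = gout.reshape(B, g, Og, oh, ow)
        if w.requires_grad:
            gw = _einsum("bgcijuv,bgouv->gocij", cols, go)
            _accum(w, gw.reshape(O, Cg, kh, kw))
        if b is not None and b.requires_grad:
            _accum(b, gout.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = _einsum("gocij,bgouv->bgcijuv", wg, go)
            gxp = np.zeros((B, g, Cg, Hp, Wp), dtype=xd.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :,
                        :,
                        :,
                        i * dh : i * dh + (oh - 1) * sh + 1 : sh,
                        j * dw : j * dw + (ow - 1) * sw + 1 : sw,
                    ] += gcols[:, :, :, i, j]
            gx = gxp.reshape(B, C, Hp, Wp)[:, :, ph : ph + H, pw : pw + W]
            _accum(x, gx)

    return _node(out, parents, bwd)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact ×2 upsampling).

    ``x``: (B, C, H, W); ``w``: (C, O, 2, 2); output (B, O, 2H, 2W).
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    Cw, O, kh, kw = wd.shape
    if C != Cw or (kh, kw) != (2, 2):
        raise ValueError(f"conv_transpose2x: weight {wd.shape} incompatible with input {xd.shape}")
    out = _einsum("bcuv,coij->bouivj", xd, wd).reshape(B, O, 2 * H, 2 * W)
    if b is not None:
        out = out + b.data.reshape(1, O, 1, 1)
    _flops(2.0 * B * C * O * 4 * H * W)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(gout):
        go = gout.reshape(B, O, H, 2, W, 2)
        if w.requires_grad:
            _accum(w, _einsum("bcuv,bouivj->coij", xd, go))
        if b is not None and b.requires_grad:
            _accum(b, gout.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            _accum(x, _einsum("coij,bouivj->bcuv", wd, go))

    return _node(out, parents, bwd)


# ---- bilinear interpolation ------------------------------------------------


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic matrix mapping n_in samples to n_out (align_corners)."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    if n_out == 1:
        M[0, 0] = 1.0
        return M
    pos = np.arange(n_out, dtype=np.float64) * (n_in - 1) / (n_out - 1)
    lo = np.minimum(np.floor(pos).astype(int), n_in - 2)
    frac = pos - lo
    M[np.arange(n_out), lo] = 1.0 - frac
    M[np.arange(n_out), lo + 1] += frac
    return M


def bilinear_resize(a: Tensor, size) -> Tensor:
    """Bilinear resize of the trailing two axes to ``size`` (align_corners)."""
    oh, ow = int(size[0]), int(size[1])
    if oh < 1 or ow < 1:
        raise ValueError(f"bilinear target extent must be >= 1, got {(oh, ow)}")
    ih, iw = a.shape[-2], a.shape[-1]
    Mh = _interp_matrix(ih, oh, a.data.dtype)
    Mw = _interp_matrix(iw, ow, a.data.dtype)
    out = _einsum("...yx,hy,wx->...hw", a.data, Mh, Mw)
    _flops(8.0 * out.size)

    def bwd(g):
        _accum(a, _einsum("...hw,hy,wx->...yx", g, Mh, Mw))

    return _node(out, (a,), bwd)
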