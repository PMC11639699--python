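"""Independent reference implementations used as test oracles.

Everything here is written as straight-line numpy with explicit scalar loops
over output positions — deliberately sharing no code with the package's
vectorized im2col/einsum implementations — so agreement between the two is
meaningful evidence of correctness.  Only usable on tiny tensors.
"""

from __future__ import annotations

import math

import numpy as np


def sigmoid_ref(x):
    return 1.0 / (1.0 + np.exp(-x))


def swish_ref(x):
    return x * sigmoid_ref(x)


def gelu_ref(x):
    return x * 0.5 * (1.0 + np.vectorize(math.erf)(x / math.sqrt(2.0)))


def leaky_ref(x, slope=0.01):
    return np.where(x >= 0, x, slope * x)


def conv2d_ref(x, w, b=None, stride=1, padding=0, dilation=1, groups=1):
    """Naive scalar-loop 2-D cross-correlation."""
    s = stride if isinstance(stride, tuple) else (stride, stride)
    p = padding if isinstance(padding, tuple) else (padding, padding)
    d = dilation if isinstance(dilation, tuple) else (dilation, dilation)
    B, C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p[0], p[0]), (p[1], p[1])))
    Hp, Wp = xp.shape[2:]
    oh = (Hp - (kh - 1) * d[0] - 1) // s[0] + 1
    ow = (Wp - (kw - 1) * d[1] - 1) // s[1] + 1
    Og = O // groups
    out = np.zeros((B, O, oh, ow))
    for bb in range(B):
        for o in range(O):
            grp = o // Og
            for u in range(oh):
                for v in range(ow):
                    acc = 0.0 if b is None else float(b[o])
                    for c in range(Cg):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (
                                    xp[bb, grp * Cg + c, u * s[0] + i * d[0], v * s[1] + j * d[1]]
                                    * w[o, c, i, j]
                                )
                    out[bb, o, u, v] = acc
    return out


def batchnorm_train_ref(x, gamma, beta, eps=1e-5):
    """Training-mode batch norm: biased batch statistics over (B, H, W)."""
    mu = x.mean(axis=(0, 2, 3), keepdims=True)
    var = x.var(axis=(0, 2, 3), keepdims=True)
    xhat = (x - mu) / np.sqrt(var + eps)
    return xhat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def instancenorm_ref(x, eps=1e-5):
    out = np.empty_like(x)
    for bb in range(x.shape[0]):
        for c in range(x.shape[1]):
            sl = x[bb, c]
            out[bb, c] = (sl - sl.mean()) / np.sqrt(sl.var() + eps)
    return out


def groupnorm_ref(x, groups, gamma, beta, eps=1e-5):
    B, C, H, W = x.shape
    cg = C // groups
    out = np.empty_like(x)
    for bb in range(B):
        for g in range(groups):
            sl = x[bb, g * cg : (g + 1) * cg]
            out[bb, g * cg : (g + 1) * cg] = (sl - sl.mean()) / np.sqrt(sl.var() + eps)
    return out * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1)


def bilinear_resize_ref(x, size):
    """Align-corners bilinear resize of the trailing two axes, scalar loops."""
    oh, ow = size
    ih, iw = x.shape[-2:]
    lead = x.shape[:-2]
    flat = x.reshape((-1, ih, iw))
    out = np.zeros((flat.shape[0], oh, ow))
    for n in range(flat.shape[0]):
        for u in range(oh):
            fy = 0.0 if oh == 1 or ih == 1 else u * (ih - 1) / (oh - 1)
            y0 = min(int(math.floor(fy)), ih - 2) if ih > 1 else 0
            ty = fy - y0
            for v in range(ow):
                fx = 0.0 if ow == 1 or iw == 1 else v * (iw - 1) / (ow - 1)
                x0 = min(int(math.floor(fx)), iw - 2) if iw > 1 else 0
                tx = fx - x0
                if ih == 1 and iw == 1:
                    out[n, u, v] = flat[n, 0, 0]
                elif ih == 1:
                    out[n, u, v] = (1 - tx) * flat[n, 0, x0] + tx * flat[n, 0, x0 + 1]
                elif iw == 1:
                    out[n, u, v] = (1 - ty) * flat[n, y0, 0] + ty * flat[n, y0 + 1, 0]
                else:
                    out[n, u, v] = (
                        (1 - ty) * (1 - tx) * flat[n, y0, x0]
                        + (1 - ty) * tx * flat[n, y0, x0 + 1]
                        + ty * (1 - tx) * flat[n, y0 + 1, x0]
                        + ty * tx * flat[n, y0 + 1, x0 + 1]
                    )
    return out.reshape(lead + (oh, ow))


# ---- module-level oracles ---------------------------------------------------


def _p(module, name):
    """Fetch a parameter/buffer value by dotted name from a Module."""
    sd = module.state_dict()
    return np.asarray(sd[name], dtype=np.float64)


def lfe_ref(x, lfe):
    """Steps (i)-(v) of the dual 1-D pooled gating attention, training mode."""
    b, C, h, w = x.shape
    pool_h = x.mean(axis=3, keepdims=True)                 # (b, C, h, 1)
    pool_w = x.mean(axis=2, keepdims=True)                 # (b, C, 1, w)
    strip = np.concatenate([pool_h, pool_w.transpose(0, 1, 3, 2)], axis=2)
    mid = conv2d_ref(strip, _p(lfe, "conv_mid.weight"), _p(lfe, "conv_mid.bias"))
    mid = batchnorm_train_ref(mid, _p(lfe, "bn.weight"), _p(lfe, "bn.bias"))
    mid = swish_ref(mid)
    mid_h = mid[:, :, :h, :]
    mid_w = mid[:, :, h:, :].transpose(0, 1, 3, 2)
    g_h = sigmoid_ref(conv2d_ref(mid_h, _p(lfe, "gate_h.weight"), _p(lfe, "gate_h.bias")))
    g_w = sigmoid_ref(conv2d_ref(mid_w, _p(lfe, "gate_w.weight"), _p(lfe, "gate_w.bias")))
    return x * g_h * g_w


def hpa_ref(x, hpa):
    """Bilinear-resize + depthwise 3×3 + Hadamard product, all by loops."""
    a1, a2 = x.shape[-2:]
    p = _p(hpa, "p")
    depth = p.shape[0]
    resized = bilinear_resize_ref(p, (a1, a2))
    gate = conv2d_ref(
        resized[None],
        _p(hpa, "dw_weight"),
        _p(hpa, "dw_bias"),
        padding=1,
        groups=depth,
    )[0]
    return x * gate


def lce_contrast_ref(f_local, f_context, slope=0.01, eps=1e-5):
    return leaky_ref(instancenorm_ref(f_local - f_context, eps), slope)


def _seq_ref(x, seq_module, spec):
    """Run a Sequential of convs/BNs/activations per a (kind, name, kwargs) layout list."""
    out = x
    for kind, name, kw in spec:
        if kind == "conv":
            out = conv2d_ref(
                out, _p(seq_module, f"{name}.weight"), _p(seq_module, f"{name}.bias"), **kw
            )
        elif kind == "bn":
            out = batchnorm_train_ref(
                out, _p(seq_module, f"{name}.weight"), _p(seq_module, f"{name}.bias")
            )
        elif kind == "gelu":
            out = gelu_ref(out)
    return out


def lsa_ref(f_c, lsa, final_dilation=7, slope=0.01):
    """Literal four-branch + shortcut re-implementation (training mode)."""
    d = final_dilation
    b1 = _seq_ref(f_c, lsa.b1, [("conv", "0", {}), ("bn", "1", {})])
    b2 = _seq_ref(
        f_c,
        lsa.b2,
        [
            ("conv", "0", {}), ("bn", "1", {}), ("gelu", None, {}),
            ("conv", "3", {"padding": 3}), ("bn", "4", {}), ("gelu", None, {}),
            ("conv", "6", {"padding": d, "dilation": d}), ("bn", "7", {}),
        ],
    )
    deep_spec = [
        ("conv", "0", {}), ("bn", "1", {}), ("gelu", None, {}),
        ("conv", "3", {"padding": 3}), ("bn", "4", {}), ("gelu", None, {}),
        ("conv", "6", {"padding": 3}), ("bn", "7", {}), ("gelu", None, {}),
        ("conv", "9", {"padding": d, "dilation": d}), ("bn", "10", {}),
    ]
    b3 = _seq_ref(f_c, lsa.b3, deep_spec)
    b4 = _seq_ref(f_c, lsa.b4, deep_spec)
    f_t = np.concatenate([b1, b2, b3, b4], axis=1)
    fused = _seq_ref(f_t, lsa.fuse, [("conv", "0", {"padding": d, "dilation": d}), ("bn", "1", {})])
    short = _seq_ref(f_c, lsa.shortcut, [("conv", "0", {}), ("bn", "1", {})])
    return leaky_ref(fused + short, slope)


def fhpa_ref(x, block):
    """Group-norm → chunk → three-axis HPA + depthwise path → re-fuse."""
    cfg = block.config
    C = cfg.channels
    G = C // 4
    z = groupnorm_ref(x, cfg.gn_groups, _p(block, "gn_in.weight"), _p(block, "gn_in.bias"))
    x1, x2, x3, x4 = (z[:, i * G : (i + 1) * G] for i in range(4))
    y1 = hpa_ref(x1, block.hpa_xy)
    y2 = hpa_ref(x2.transpose(0, 3, 1, 2), block.hpa_zx).transpose(0, 2, 3, 1)
    y3 = hpa_ref(x3.transpose(0, 2, 1, 3), block.hpa_zy).transpose(0, 2, 1, 3)
    y4 = conv2d_ref(x4, _p(block, "g4.0.weight"), _p(block, "g4.0.bias"))
    y4 = gelu_ref(y4)
    y4 = conv2d_ref(y4, _p(block, "g4.2.weight"), _p(block, "g4.2.bias"), padding=1, groups=G)
    fused = np.concatenate([y1, y2, y3, y4], axis=1)
    fused = groupnorm_ref(fused, cfg.gn_groups, _p(block, "gn_out.weight"), _p(block, "gn_out.bias"))
    out = conv2d_ref(fused, _p(block, "out_path.0.weight"), _p(block, "out_path.0.bias"), padding=1, groups=C)
    out = gelu_ref(out)
    return conv2d_ref(out, _p(block, "out_path.2.weight"), _p(block, "out_path.2.bias"))


def hausdorff_percentile_ref(a, b, percentile=95.0):
    """Brute-force all-pairs directed-distance percentile Hausdorff."""
    pa = np.argwhere(np.asarray(a, dtype=bool))
    pb = np.argwhere(np.asarray(b, dtype=bool))
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2).astype(np.float64)
    d_ab = np.sqrt(d2.min(axis=1))
    d_ba = np.sqrt(d2.min(axis=0))
    return max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
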