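"""Convolution and resampling primitives with hand-written gradients.

Convolutions are evaluated tap-by-tap: a k^3 kernel becomes k^3 matrix
multiplications against shifted views of the padded input.  This keeps peak
memory at one activation-sized buffer per tap and routes the arithmetic
through BLAS.
"""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, is_grad_enabled
from ._kernels import im2col3, release_buffer

__all__ = ["conv3d", "conv2d_depthwise", "upsample_linear2", "pad_spatial"]


def _pad(x: np.ndarray, pad: tuple, spatial_start: int) -> np.ndarray:
    if all(p == 0 for p in pad):
        return x
    shape = list(x.shape)
    sl = [slice(None)] * spatial_start
    for i, p in enumerate(pad):
        shape[spatial_start + i] += 2 * p
        sl.append(slice(p, p + x.shape[spatial_start + i]))
    out = np.zeros(shape, dtype=x.dtype)
    out[tuple(sl)] = x
    return out


def _conv3d_raw(x: np.ndarray, w: np.ndarray, stride: int, padding: int,
                want_cols: bool = False):
    """Forward 3D cross-correlation on raw arrays.

    Returns (out, cols); ``cols`` is the tap-major im2col buffer of shape
    (B, k^3 * Ci, S) when requested on the stride-1 path, else None.
    """
    B, Ci, X, Y, Z = x.shape
    Co, _, kx, ky, kz = w.shape
    if kx == ky == kz == 1:
        xs = x[:, :, ::stride, ::stride, ::stride] if stride != 1 else x
        sh = xs.shape
        out = np.matmul(w.reshape(Co, Ci), xs.reshape(B, Ci, -1))
        return out.reshape(B, Co, *sh[2:]), None
    xp = _pad(x, (padding,) * 3, 2)
    Xo = (X + 2 * padding - kx) // stride + 1
    Yo = (Y + 2 * padding - ky) // stride + 1
    Zo = (Z + 2 * padding - kz) // stride + 1
    S = Xo * Yo * Zo
    if stride == 1 and kx == ky == kz:
        nt = kx * ky * kz
        colsm = im2col3(np.ascontiguousarray(xp), kx).reshape(B, nt * Ci, S)
        wm = np.ascontiguousarray(
            w.transpose(0, 2, 3, 4, 1)).reshape(Co, nt * Ci)
        out = np.matmul(wm, colsm).reshape(B, Co, Xo, Yo, Zo)
        if want_cols:
            return out, colsm
        release_buffer(colsm)
        return out, None
    out = np.zeros((B, Co, Xo, Yo, Zo), dtype=np.float32)
    s = stride
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                xs = xp[:, :, i:i + s * Xo:s, j:j + s * Yo:s, k:k + s * Zo:s]
                out += np.einsum("oc,bcxyz->boxyz", w[:, :, i, j, k], xs,
                                 optimize=True)
    return out, None


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 1) -> Tensor:
    """3D cross-correlation.

    Parameters
    ----------
    x : Tensor, shape (B, Cin, X, Y, Z)
    weight : Tensor, shape (Cout, Cin, kx, ky, kz)
    bias : Tensor of shape (Cout,) or None
    stride, padding : int, applied to all three spatial axes

    Stride-1 k>1 convolutions run through a tap-major im2col GEMM; the input
    gradient is evaluated as a transposed convolution through the same fast
    path.  1x1x1 convolutions reduce to a single channel-mixing GEMM.
    """
    B, Ci, X, Y, Z = x.shape
    Co, Ci_w, kx, ky, kz = weight.shape
    if Ci != Ci_w:
        raise ValueError(f"channel mismatch: input has {Ci}, kernel expects {Ci_w}")
    need_grad = (x.requires_grad or weight.requires_grad) and is_grad_enabled()
    out, cols = _conv3d_raw(x.data, weight.data, stride, padding,
                            want_cols=need_grad and weight.requires_grad
                            and stride == 1 and kx > 1)
    w = weight.data
    if bias is not None:
        out += bias.data.reshape(1, Co, 1, 1, 1)
    Xo, Yo, Zo = out.shape[2:]
    parents = [x, weight] + ([bias] if bias is not None else [])
    pointwise = kx == ky == kz == 1

    def bw(g):
        S = Xo * Yo * Zo
        gm = g.reshape(B, Co, S)
        if pointwise:
            if weight.requires_grad:
                gw = np.zeros((Co, Ci), np.float32)
                xs = (x.data if stride == 1 else
                      x.data[:, :, ::stride, ::stride, ::stride])
                xm = xs.reshape(B, Ci, S)
                for b in range(B):
                    gw += gm[b] @ xm[b].T
                weight._accum(gw.reshape(w.shape))
            if x.requires_grad:
                gx = np.matmul(w.reshape(Co, Ci).T, gm)
                if stride == 1:
                    x._accum(gx.reshape(x.shape))
                else:
                    full = np.zeros_like(x.data)
                    full[:, :, ::stride, ::stride, ::stride] = \
                        gx.reshape(B, Ci, Xo, Yo, Zo)
                    x._accum(full)
        elif stride == 1 and kx == ky == kz:
            if weight.requires_grad:
                c = cols
                if c is None:  # rebuilt only if forward skipped caching
                    _, c = _conv3d_raw(x.data, w, 1, padding, want_cols=True)
                gw = np.zeros((Co, c.shape[1]), np.float32)
                for b in range(B):
                    gw += gm[b] @ c[b].T
                release_buffer(c)
                gw = gw.reshape(Co, kx, ky, kz, Ci).transpose(0, 4, 1, 2, 3)
                weight._accum(np.ascontiguousarray(gw))
            if x.requires_grad:
                # transposed conv: correlate g with the flipped, transposed
                # kernel (valid for padding == k//2)
                wt = np.ascontiguousarray(
                    w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
                gx, _ = _conv3d_raw(g, wt, 1, padding)
                x._accum(gx)
        else:
            xp = _pad(x.data, (padding,) * 3, 2)
            if weight.requires_grad:
                gw = np.zeros_like(w)
            gxp = np.zeros_like(xp) if x.requires_grad else None
            s = stride
            for i in range(kx):
                for j in range(ky):
                    for k in range(kz):
                        sl = (slice(None), slice(None),
                              slice(i, i + s * Xo, s),
                              slice(j, j + s * Yo, s),
                              slice(k, k + s * Zo, s))
                        if weight.requires_grad:
                            gw[:, :, i, j, k] = np.einsum(
                                "boxyz,bcxyz->oc", g, xp[sl], optimize=True)
                        if gxp is not None:
                            gxp[sl] += np.einsum(
                                "oc,boxyz->bcxyz", w[:, :, i, j, k], g,
                                optimize=True)
            if weight.requires_grad:
                weight._accum(gw)
            if gxp is not None:
                if padding:
                    gxp = gxp[:, :, padding:padding + X, padding:padding + Y,
                              padding:padding + Z]
                x._accum(gxp)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(out, parents, bw)


def conv2d_depthwise(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     padding: tuple = (0, 0)) -> Tensor:
    """Depthwise 2D cross-correlation (one kernel per channel, stride 1).

    x : (B, C, H, W); weight : (C, kh, kw); padding : (ph, pw).
    """
    B, C, H, W = x.shape
    Cw, kh, kw = weight.shape
    if C != Cw:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    ph, pw = padding
    xp = _pad(x.data, (ph, pw), 2)
    Ho = H + 2 * ph - kh + 1
    Wo = W + 2 * pw - kw + 1
    out = np.zeros((B, C, Ho, Wo), dtype=np.float32)
    w = weight.data
    for i in range(kh):
        for j in range(kw):
            out += w[None, :, i, j, None, None] * xp[:, :, i:i + Ho, j:j + Wo]
    if bias is not None:
        out += bias.data.reshape(1, C, 1, 1)

    parents = [x, weight] + ([bias] if bias is not None else [])

    def bw(g):
        if weight.requires_grad:
            gw = np.zeros_like(w)
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + Ho, j:j + Wo]
                if weight.requires_grad:
                    gw[:, i, j] = (g * xs).sum(axis=(0, 2, 3))
                if gxp is not None:
                    gxp[:, :, i:i + Ho, j:j + Wo] += \
                        w[None, :, i, j, None, None] * g
        if weight.requires_grad:
            weight._accum(gw)
        if gxp is not None:
            gx = gxp
            if ph or pw:
                gx = gxp[:, :, ph:ph + H, pw:pw + W]
            x._accum(gx)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, bw)


def _up2_matrix(n: int, dtype=np.float32) -> np.ndarray:
    """Interpolation matrix for linear x2 upsampling (half-pixel centers).

    Output sample 2i sits at input coordinate i - 0.25, sample 2i+1 at
    i + 0.25, with edge clamping; identical to the usual align_corners=False
    convention for scale factor 2.
    """
    m = np.zeros((2 * n, n), dtype=dtype)
    for o in range(2 * n):
        pos = (o + 0.5) / 2.0 - 0.5
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        m[o, lo_c] += 1.0 - frac
        m[o, hi_c] += frac
    return m


def upsample_linear2(x: Tensor, axes: tuple) -> Tensor:
    """Differentiable linear 2x upsampling along the given axes."""
    out_data = x.data
    mats = []
    for ax in axes:
        m = _up2_matrix(out_data.shape[ax], out_data.dtype)
        out_data = np.moveaxis(
            np.tensordot(m, np.moveaxis(out_data, ax, 0), axes=(1, 0)), 0, ax)
        mats.append((ax, m))

    def bw(g):
        for ax, m in reversed(mats):
            g = np.moveaxis(
                np.tensordot(m.T, np.moveaxis(g, ax, 0), axes=(1, 0)), 0, ax)
        x._accum(g.astype(x.data.dtype))

    return Tensor._make(out_data, (x,), bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
               stats: tuple | None = None, relu: bool = False):
    """Fused batch normalization over (batch, spatial) per channel,
    optionally with a fused ReLU.

    With ``stats=None`` (training) the batch statistics are used and
    returned alongside the output; with ``stats=(mean, var)`` (inference)
    the given running statistics are applied.  The backward pass uses the
    closed-form batch-norm gradient rather than composing primitives.
    """
    axes = (0,) + tuple(range(2, x.ndim))
    C = x.shape[1]
    bshape = (1, C) + (1,) * (x.ndim - 2)
    xd = x.data
    if stats is None:
        # moments via E[x^2] - E[x]^2 with float64 accumulation
        mu64 = xd.mean(axis=axes, dtype=np.float64)
        var64 = (xd * xd).mean(axis=axes, dtype=np.float64) - mu64 ** 2
        mu = mu64.astype(np.float32)
        var = np.maximum(var64, 0.0).astype(np.float32)
    else:
        mu, var = stats
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (xd - mu.reshape(bshape).astype(np.float32)) \
        * inv_std.reshape(bshape)
    out = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
    if relu:
        np.maximum(out, 0, out=out)

    def bw(g):
        if relu:
            g = g * (out > 0)
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if not x.requires_grad:
            return
        gxh = g * gamma.data.reshape(bshape)
        if stats is not None:
            x._accum(gxh * inv_std.reshape(bshape))
            return
        n = xd.size // C
        s1 = gxh.sum(axis=axes).reshape(bshape)
        s2 = (gxh * xhat).sum(axis=axes).reshape(bshape)
        dx = (gxh - s1 / n - xhat * (s2 / n)) * inv_std.reshape(bshape)
        x._accum(dx.astype(np.float32))

    out_t = Tensor._make(out, (x, gamma, beta), bw)
    if stats is None:
        return out_t, (mu, var)
    return out_t


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable voxel-mean binary cross-entropy on logits.

    Uses log(1 + exp(-|z|)) + max(z, 0) - z*y in one pass; the gradient is
    (sigmoid(z) - y) / N.
    """
    t = np.asarray(target.data if isinstance(target, Tensor) else target,
                   dtype=np.float32)
    z = logits.data
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch: logits {z.shape} vs target {t.shape}")
    n = float(z.size)
    val = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).sum() / n

    def bw(g):
        from scipy.special import expit
        logits._accum((g * (expit(z) - t) / n).astype(np.float32))

    return Tensor._make(np.float32(val), (logits,), bw)


def pad_spatial(x: Tensor, pad_width) -> Tensor:
    """Zero-pad trailing spatial axes; pad_width like numpy's, full rank."""
    pw = tuple(tuple(p) for p in pad_width)

    def bw(g):
        sl = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(pw))
        x._accum(g[sl])

    return Tensor._make(np.pad(x.data, pw), (x,), bw)
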