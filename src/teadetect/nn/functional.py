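"""Array-level neural primitives: convolution, pooling, sampling.

All functions take and return :class:`~teadetect.nn.tensor.Tensor` in NCHW
layout and register hand-written vector-Jacobian products on the tape.
Convolution is lowered to an im2col matrix product; its backward pass is the
matching col2im scatter.  ``gather_pixels`` is the integer-indexed read used
by the bilinear sampler of the deformable convolution.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, _GradMode

__all__ = ["conv2d", "max_pool2d", "upsample_nearest2x", "gather_pixels"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (cols, (Ho, Wo)) with cols of shape (N, C*kh*kw, Ho*Wo)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sn, sc, sh, sw = x.strides
    windows = as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(n, c * kh * kw, ho * wo)
    return cols, (ho, wo)


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
    dcols = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                dcols[:, :, i, j]
            )
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, same-padding by default."""
    co, ci, kh, kw = weight.data.shape
    if pad is None:
        pad = kh // 2
    n = x.data.shape[0]
    cols, (ho, wo) = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = np.matmul(wmat, cols)  # (n, co, ho*wo) via broadcasting
    if bias is not None:
        out = out + bias.data[:, None]
    out = out.reshape(n, co, ho, wo)

    parents = (x, weight) if bias is None else (x, weight, bias)
    needs_tape = _GradMode.enabled and any(p.requires_grad for p in parents)
    if not needs_tape:
        return Tensor(out)

    x_shape = x.data.shape

    def backward(g):
        gmat = g.reshape(n, co, ho * wo)
        if weight.requires_grad:
            dw = np.einsum("nop,ncp->oc", gmat, cols, optimize=True)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)
            x._accum(_col2im(dcols, x_shape, kh, kw, stride, pad))

    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, pad: int | None = None) -> Tensor:
    """Max pooling with -inf padding (stride-1 pad k//2 keeps the shape)."""
    if pad is None:
        pad = kernel // 2
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    hp, wp = xp.shape[2:]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    sn, sc, sh, sw = xp.strides
    windows = as_strided(
        xp,
        shape=(n, c, ho, wo, kernel, kernel),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )
    flat = np.ascontiguousarray(windows).reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    if not (_GradMode.enabled and x.requires_grad):
        return Tensor(out)

    def backward(g):
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        ki, kj = np.divmod(arg, kernel)
        ii = np.arange(ho)[:, None] * stride + ki
        jj = np.arange(wo)[None, :] * stride + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        x._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

    return Tensor._make(out, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def gather_pixels(x: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """Read ``x[n, :, iy, ix]`` with zero padding outside the image.

    ``iy``/``ix`` are integer index arrays of shape (N, K, H, W); the result
    has shape (N, C, K, H, W).  Gradient w.r.t. ``x`` is a scatter-add; the
    indices are constants (the sampler differentiates through the bilinear
    weights, not the lattice points).
    """
    n, c, h, w = x.data.shape
    valid = (iy >= 0) & (iy < h) & (ix >= 0) & (ix < w)
    iyc = np.clip(iy, 0, h - 1)
    ixc = np.clip(ix, 0, w - 1)
    nn = np.arange(n)[:, None, None, None]
    out = x.data[nn, :, iyc, ixc]          # (N, K, H, W, C)
    out = np.moveaxis(out, -1, 1)          # (N, C, K, H, W)
    out = out * valid[:, None].astype(np.float32)

    if not (_GradMode.enabled and x.requires_grad):
        return Tensor(out)

    def backward(g):
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        gm = np.moveaxis(g * valid[:, None], 1, -1)  # (N, K, H, W, C)
        np.add.at(x.grad, (nn, slice(None), iyc, ixc), gm)

    return Tensor._make(out, (x,), backward)
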