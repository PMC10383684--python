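"""Detector building blocks.

The pieces assembled by :mod:`teadetect.model`:

* ``ConvBNSiLU`` (CBS) — convolution, batch norm, SiLU (re-exported from the
  nn core);
* ``C2f`` — cross-stage-partial block: a 1x1 conv splits channels in two,
  ``n`` residual bottlenecks are chained on the second half with every
  intermediate retained, and all parts are re-fused by a 1x1 conv;
* ``DeformConv2d`` — modulated deformable convolution (DCNv2): a sibling 3x3
  conv predicts per-location sampling offsets and sigmoid modulation masks
  (2K + K channels for K = 9), and the main kernel samples the input at the
  displaced positions by bilinear interpolation,
  y(p) = sum_k w_k * x(p + p_k + dp_k) * dm_k;
* ``C2fDCN`` — C2f with both bottleneck 3x3 convolutions deformable;
* ``GAM`` — global attention: a channel gate (permute channels last, two-layer
  perceptron C -> C/r -> C, sigmoid) followed by a spatial gate (7x7 conv
  C -> C/r with BN+ReLU, 7x7 conv back to C with BN, sigmoid), both applied
  multiplicatively, with no pooling anywhere;
* ``SPPF`` / ``SPPFCSPC`` — spatial pyramid pooling; three chained 5x5
  stride-1 max pools reproduce parallel 5/9/13 kernels, the CSPC variant
  wrapping the cascade in a cross-stage-partial 7-convolution topology.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, functional as F
from .nn.layers import ConvBNSiLU, Conv2d, BatchNorm2d, Linear, Module, ModuleList

__all__ = [
    "ConvBNSiLU",
    "Bottleneck",
    "C2f",
    "DeformConv2d",
    "BottleneckDCN",
    "C2fDCN",
    "GAM",
    "SPPF",
    "SPPFCSPC",
]


def _rng(rng):
    return rng if rng is not None else np.random.default_rng(0)


class Bottleneck(Module):
    """Two 3x3 CBS convs with an optional residual connection."""

    def __init__(self, c_in, c_out, shortcut=True, e=1.0, rng=None):
        super().__init__()
        rng = _rng(rng)
        c_hidden = int(c_out * e)
        self.cv1 = ConvBNSiLU(c_in, c_hidden, 3, rng=rng)
        self.cv2 = ConvBNSiLU(c_hidden, c_out, 3, rng=rng)
        self.add = shortcut and c_in == c_out

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    def __init__(self, c_in, c_out, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        if c_out % 2:
            raise ValueError("C2f output channels must be even")
        rng = _rng(rng)
        self.c = int(c_out * e)
        self.cv1 = ConvBNSiLU(c_in, 2 * self.c, 1, rng=rng)
        self.cv2 = ConvBNSiLU((2 + n) * self.c, c_out, 1, rng=rng)
        self.m = ModuleList(
            self._bottleneck(self.c, self.c, shortcut, rng) for _ in range(n)
        )

    @staticmethod
    def _bottleneck(c_in, c_out, shortcut, rng):
        return Bottleneck(c_in, c_out, shortcut, e=1.0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        first = y[:, : self.c]
        parts = [first, y[:, self.c :]]
        for m in self.m:
            parts.append(m(parts[-1]))
        return self.cv2(nn.concat(parts, axis=1))


class DeformConv2d(Module):
    """Modulated deformable 3x3 convolution (stride 1, same padding).

    The offset/mask branch is zero-initialized (mask logits biased far into
    sigmoid saturation) so an untrained layer matches the dense convolution
    with its base kernel to float precision.
    """

    K = 9  # 3x3 sampling grid
    _MASK_BIAS = 12.0  # sigmoid(12) = 1 - 6e-6: unit modulation at init

    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        rng = _rng(rng)
        self.c_in, self.c_out = c_in, c_out
        self.conv = Conv2d(c_in, c_out, 3, bias=True, rng=rng)
        self.offset_mask = Conv2d(c_in, 3 * self.K, 3, bias=True, rng=rng)
        self.offset_mask.weight.data[...] = 0.0
        self.offset_mask.bias.data[...] = 0.0
        self.offset_mask.bias.data[2 * self.K :] = self._MASK_BIAS
        # base 3x3 grid, row-major: (-1,-1) .. (1,1)
        grid = np.stack(np.meshgrid([-1, 0, 1], [-1, 0, 1], indexing="ij"), -1)
        self._base = grid.reshape(self.K, 2).astype(np.float32)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        h, w = x.shape[2:]
        om = self.offset_mask(x)
        off = om[:, : 2 * self.K].reshape(n, self.K, 2, h, w)
        mask = om[:, 2 * self.K :].sigmoid()  # (N, K, H, W)
        return self.sample(x, off, mask)

    def sample(self, x: Tensor, off: Tensor, mask: Tensor) -> Tensor:
        """Deformable sampling with explicit offsets (N,K,2,H,W) and masks."""
        n, c, h, w = x.shape
        if not np.isfinite(off.data).all():
            raise FloatingPointError("non-finite deformable offsets")

        gy = np.arange(h, dtype=np.float32)[:, None]
        gx = np.arange(w, dtype=np.float32)[None, :]
        base_y = self._base[:, 0][None, :, None, None] + gy[None, None]
        base_x = self._base[:, 1][None, :, None, None] + gx[None, None]
        py = off[:, :, 0] + Tensor(base_y)  # (N, K, H, W)
        px = off[:, :, 1] + Tensor(base_x)

        y0 = np.floor(py.data).astype(np.int64)
        x0 = np.floor(px.data).astype(np.int64)
        fy = py - Tensor(y0.astype(np.float32))
        fx = px - Tensor(x0.astype(np.float32))

        v00 = F.gather_pixels(x, y0, x0)
        v01 = F.gather_pixels(x, y0, x0 + 1)
        v10 = F.gather_pixels(x, y0 + 1, x0)
        v11 = F.gather_pixels(x, y0 + 1, x0 + 1)

        fy = fy.reshape(n, 1, self.K, h, w)
        fx = fx.reshape(n, 1, self.K, h, w)
        one = Tensor(np.float32(1.0))
        val = (
            v00 * (one - fy) * (one - fx)
            + v01 * (one - fy) * fx
            + v10 * fy * (one - fx)
            + v11 * fy * fx
        )
        val = val * mask.reshape(n, 1, self.K, h, w)

        # weighted sum over (C_in, K): matmul with the kernel as a matrix
        cols = val.reshape(n, self.c_in * self.K, h * w)
        wmat = self.conv.weight.reshape(self.c_out, self.c_in * self.K)
        out = wmat @ cols
        out = out + self.conv.bias.reshape(1, self.c_out, 1)
        return out.reshape(n, self.c_out, h, w)


class BottleneckDCN(Module):
    """Bottleneck with both 3x3 convolutions deformable (BN + SiLU kept)."""

    def __init__(self, c_in, c_out, shortcut=True, rng=None):
        super().__init__()
        rng = _rng(rng)
        self.cv1 = DeformConvBNSiLU(c_in, c_out, rng=rng)
        self.cv2 = DeformConvBNSiLU(c_out, c_out, rng=rng)
        self.add = shortcut and c_in == c_out

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class DeformConvBNSiLU(Module):
    def __init__(self, c_in, c_out, rng=None):
        super().__init__()
        rng = _rng(rng)
        self.conv = DeformConv2d(c_in, c_out, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class C2fDCN(C2f):
    """C2f whose bottleneck convolutions are modulated deformable convs."""

    @staticmethod
    def _bottleneck(c_in, c_out, shortcut, rng):
        return BottleneckDCN(c_in, c_out, shortcut, rng=rng)


class GAM(Module):
    def __init__(self, channels, reduction=4, rng=None):
        super().__init__()
        if channels % reduction:
            raise ValueError("channels must be divisible by the reduction ratio")
        rng = _rng(rng)
        hidden = channels // reduction
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)
        self.sconv1 = Conv2d(channels, hidden, 7, bias=False, rng=rng)
        self.sbn1 = BatchNorm2d(hidden)
        self.sconv2 = Conv2d(hidden, channels, 7, bias=False, rng=rng)
        self.sbn2 = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        # channel gate: channels-last permute, pointwise MLP, sigmoid
        perm = x.transpose(0, 2, 3, 1)
        gate_c = self.fc2(self.fc1(perm).relu()).transpose(0, 3, 1, 2).sigmoid()
        f2 = x * gate_c
        # spatial gate: two 7x7 convolutions, no pooling
        s = self.sbn1(self.sconv1(f2)).relu()
        gate_s = self.sbn2(self.sconv2(s)).sigmoid()
        return f2 * gate_s


class SPPF(Module):
    def __init__(self, c_in, c_out, pool=5, rng=None):
        super().__init__()
        rng = _rng(rng)
        c_hidden = c_in // 2
        self.cv1 = ConvBNSiLU(c_in, c_hidden, 1, rng=rng)
        self.cv2 = ConvBNSiLU(4 * c_hidden, c_out, 1, rng=rng)
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        y = self.cv1(x)
        p1 = F.max_pool2d(y, self.pool)
        p2 = F.max_pool2d(p1, self.pool)
        p3 = F.max_pool2d(p2, self.pool)
        return self.cv2(nn.concat([y, p1, p2, p3], axis=1))


class SPPFCSPC(Module):
    """CSP-wrapped pyramid pooling (7-convolution topology, hidden width 512).

    Branch B runs 1x1 -> 3x3 -> 1x1 convs, a cascade of three 5x5 stride-1
    max pools whose outputs are all concatenated with their input, then
    1x1 -> 3x3 convs; branch A is a single 1x1 conv; the branches are
    concatenated and fused by a final 1x1 conv.
    """

    def __init__(self, c_in, c_out, c_hidden=None, pool=5, rng=None):
        super().__init__()
        rng = _rng(rng)
        c_ = c_hidden if c_hidden is not None else c_in
        self.cv1 = ConvBNSiLU(c_in, c_, 1, rng=rng)
        self.cv2 = ConvBNSiLU(c_in, c_, 1, rng=rng)   # branch A
        self.cv3 = ConvBNSiLU(c_, c_, 3, rng=rng)
        self.cv4 = ConvBNSiLU(c_, c_, 1, rng=rng)
        self.cv5 = ConvBNSiLU(4 * c_, c_, 1, rng=rng)
        self.cv6 = ConvBNSiLU(c_, c_, 3, rng=rng)
        self.cv7 = ConvBNSiLU(2 * c_, c_out, 1, rng=rng)
        self.pool = pool

    def forward(self, x: Tensor) -> Tensor:
        r = self.cv4(self.cv3(self.cv1(x)))
        s1 = F.max_pool2d(r, self.pool)
        s2 = F.max_pool2d(s1, self.pool)
        s3 = F.max_pool2d(s2, self.pool)
        b = self.cv6(self.cv5(nn.concat([r, s1, s2, s3], axis=1)))
        a = self.cv2(x)
        return self.cv7(nn.concat([a, b], axis=1))
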