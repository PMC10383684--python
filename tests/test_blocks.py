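"""Building blocks: shape contracts, degenerate equivalences, param counts.

Parameter counts are checked against analytic formulas assembled
independently of the module system (plain integer arithmetic per layer).
"""

import numpy as np
import pytest

from teadetect.nn import Tensor, functional as F
from teadetect.blocks import (
    ConvBNSiLU,
    Bottleneck,
    C2f,
    C2fDCN,
    DeformConv2d,
    GAM,
    SPPF,
    SPPFCSPC,
)


def conv_params(ci, co, k, bias=False):
    return ci * co * k * k + (co if bias else 0)


def cbs_params(ci, co, k):
    return conv_params(ci, co, k) + 2 * co  # conv (no bias) + BN scale/shift


def bottleneck_params(c):
    return cbs_params(c, c, 3) * 2


def c2f_params(ci, co, n):
    c = co // 2
    return (
        cbs_params(ci, 2 * c, 1)
        + cbs_params((2 + n) * c, co, 1)
        + n * bottleneck_params(c)
    )


def dcn_params(ci, co):
    # main kernel (with bias) + offset/mask sibling conv (27 channels, bias)
    return conv_params(ci, co, 3, bias=True) + conv_params(ci, 27, 3, bias=True)


def c2f_dcn_params(ci, co, n):
    c = co // 2
    per_bneck = 2 * (dcn_params(c, c) + 2 * c)  # two deformable convs + BN
    return (
        cbs_params(ci, 2 * c, 1)
        + cbs_params((2 + n) * c, co, 1)
        + n * per_bneck
    )


def gam_params(c, r=4):
    h = c // r
    mlp = c * h + h + h * c + c          # two linear layers with bias
    spatial = conv_params(c, h, 7) + 2 * h + conv_params(h, c, 7) + 2 * c
    return mlp + spatial


def sppf_params(c):
    return cbs_params(c, c // 2, 1) + cbs_params(2 * c, c, 1)


def sppfcspc_params(c, hidden):
    return (
        cbs_params(c, hidden, 1) * 2      # cv1 + branch-A cv2
        + cbs_params(hidden, hidden, 3)   # cv3
        + cbs_params(hidden, hidden, 1)   # cv4
        + cbs_params(4 * hidden, hidden, 1)  # cv5
        + cbs_params(hidden, hidden, 3)   # cv6
        + cbs_params(2 * hidden, c, 1)    # cv7
    )


@pytest.fixture
def x16(rng):
    return Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))


class TestConvBNSiLU:
    def test_shape_and_stride(self, rng):
        cbs = ConvBNSiLU(3, 32, 3, 2, rng=rng)
        out = cbs(Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32)))
        assert out.shape == (1, 32, 32, 32)

    def test_zero_input_spatially_constant(self, rng):
        cbs = ConvBNSiLU(3, 8, 3, rng=rng)
        cbs.eval()
        out = cbs(Tensor(np.zeros((1, 3, 6, 6), np.float32))).data
        assert np.allclose(out, out[:, :, :1, :1])

    def test_param_count(self, rng):
        assert ConvBNSiLU(3, 32, 3, rng=rng).num_parameters() == 3 * 3 * 3 * 32 + 2 * 32

    def test_channel_mismatch_raises(self, rng):
        cbs = ConvBNSiLU(4, 8, 3, rng=rng)
        with pytest.raises(ValueError):
            cbs(Tensor(np.zeros((1, 5, 6, 6), np.float32)))


class TestC2f:
    def test_shape_and_split_widths(self, rng, x16):
        for n in (1, 2):
            block = C2f(16, 16, n, rng=rng)
            assert block(x16).shape == (1, 16, 8, 8)
            # concat before the fuse conv is (2+n) * c_out/2 channels wide
            assert block.cv2.conv.weight.shape[1] == (2 + n) * 8

    def test_odd_out_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            C2f(16, 15, 1, rng=rng)

    @pytest.mark.parametrize("ci,co,n", [(16, 16, 1), (16, 16, 2), (32, 16, 3)])
    def test_param_count_matches_analytic(self, ci, co, n, rng):
        assert C2f(ci, co, n, rng=rng).num_parameters() == c2f_params(ci, co, n)


class TestDeformConv:
    def test_zero_offsets_unit_masks_match_dense_conv(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        d = DeformConv2d(1, 4, rng=rng)
        off = Tensor(np.zeros((1, 9, 2, 8, 8), np.float32))
        mask = Tensor(np.ones((1, 9, 8, 8), np.float32))
        dense = F.conv2d(x, d.conv.weight, d.conv.bias, 1, 1)
        assert np.abs(d.sample(x, off, mask).data - dense.data).max() < 1e-5

    def test_zero_masks_annihilate(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 6, 6)).astype(np.float32))
        d = DeformConv2d(2, 3, rng=rng)
        d.conv.bias.data[...] = 0.0
        off = Tensor(np.zeros((1, 9, 2, 6, 6), np.float32))
        mask = Tensor(np.zeros((1, 9, 6, 6), np.float32))
        assert np.abs(d.sample(x, off, mask).data).max() == 0.0

    def test_integer_column_shift_equals_shifted_conv(self, rng):
        """Offset (0, 1) everywhere reproduces convolving the shifted input."""
        x = rng.normal(size=(1, 2, 8, 8)).astype(np.float32)
        d = DeformConv2d(2, 3, rng=rng)
        off = np.zeros((1, 9, 2, 8, 8), np.float32)
        off[:, :, 1] = 1.0  # one column to the right
        mask = Tensor(np.ones((1, 9, 8, 8), np.float32))
        shifted = np.zeros_like(x)
        shifted[..., :-1] = x[..., 1:]
        oracle = F.conv2d(Tensor(shifted), d.conv.weight, d.conv.bias, 1, 1)
        out = d.sample(Tensor(x), Tensor(off), mask)
        interior = np.s_[:, :, 1:-1, 1:-2]
        assert np.abs(out.data[interior] - oracle.data[interior]).max() < 1e-5

    def test_non_finite_offsets_rejected(self, rng):
        d = DeformConv2d(1, 1, rng=rng)
        x = Tensor(np.zeros((1, 1, 4, 4), np.float32))
        off = np.zeros((1, 9, 2, 4, 4), np.float32)
        off[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            d.sample(x, Tensor(off), Tensor(np.ones((1, 9, 4, 4), np.float32)))

    def test_param_count(self, rng):
        assert DeformConv2d(8, 16, rng=rng).num_parameters() == dcn_params(8, 16)


class TestC2fDCN:
    def test_zero_init_offsets_reduce_to_c2f(self, rng):
        c = C2f(16, 16, 2, shortcut=True, rng=np.random.default_rng(3))
        cd = C2fDCN(16, 16, 2, shortcut=True, rng=np.random.default_rng(4))
        remap = {}
        own = dict(cd.named_parameters())
        for k, v in c.state_dict().items():
            remap[k if k in own else k.replace(".conv.weight", ".conv.conv.weight")] = v
        cd.load_state_dict(remap, strict=False)
        for name, p in cd.named_parameters():
            if name.endswith(".conv.conv.bias"):
                p.data[...] = 0.0
        c.eval(), cd.eval()
        x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
        assert np.abs(c(x).data - cd(x).data).max() < 1e-4

    def test_shape_contract_matches_c2f(self, rng, x16):
        assert C2fDCN(16, 16, 1, rng=rng)(x16).shape == (1, 16, 8, 8)

    def test_added_params_are_offset_mask_branches(self, rng):
        n, c = 2, 16
        base = C2f(c, c, n, rng=rng).num_parameters()
        dcn = C2fDCN(c, c, n, rng=rng).num_parameters()
        hidden = c // 2
        # per deformable conv: 27-channel offset/mask conv + main-kernel bias
        extra = n * 2 * (conv_params(hidden, 27, 3, bias=True) + hidden)
        assert dcn - base == extra


class TestGAM:
    def test_gates_bound_output_below_input(self, rng):
        g = GAM(16, 4, rng=rng)
        g.eval()
        x = Tensor(rng.normal(size=(2, 16, 6, 6)).astype(np.float32))
        out = g(x).data
        assert out.shape == x.shape
        assert np.all(np.abs(out) <= np.abs(x.data) + 1e-7)
        nz = np.abs(x.data) > 1e-3
        assert np.all(np.abs(out[nz]) < np.abs(x.data[nz]))  # gates < 1 strictly

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            GAM(6, 4, rng=rng)

    @pytest.mark.parametrize("c", [128, 256, 512])
    def test_param_count_matches_analytic(self, c, rng):
        assert GAM(c, 4, rng=rng).num_parameters() == gam_params(c, 4)

    def test_insertion_trio_reproduces_reported_extra(self, rng):
        # the three insertions at 128/256/512 channels total ~8.6 M
        total = sum(gam_params(c, 4) for c in (128, 256, 512))
        assert round(total / 1e6, 1) == 8.6


class TestPyramidPooling:
    def test_cascade_equals_parallel_pools(self, rng):
        x = Tensor(rng.integers(0, 100, (1, 3, 16, 16)).astype(np.float32))
        p1 = F.max_pool2d(x, 5)
        p2 = F.max_pool2d(p1, 5)
        p3 = F.max_pool2d(p2, 5)
        assert np.array_equal(p2.data, F.max_pool2d(x, 9).data)
        assert np.array_equal(p3.data, F.max_pool2d(x, 13).data)

    def test_sppf_constant_input_constant_pool_stage(self, rng):
        x = Tensor(np.full((1, 16, 8, 8), 3.0, np.float32))
        s = SPPF(16, 16, rng=rng)
        s.eval()
        out = s(x).data
        assert np.allclose(out, out[:, :, :1, :1], atol=1e-5)

    def test_shapes_preserved(self, rng, x16):
        assert SPPF(16, 16, rng=rng)(x16).shape == (1, 16, 8, 8)
        assert SPPFCSPC(16, 16, rng=rng)(x16).shape == (1, 16, 8, 8)

    def test_sppf_param_count(self, rng):
        assert SPPF(512, 512, rng=rng).num_parameters() == sppf_params(512)

    def test_sppfcspc_excess_over_sppf_at_backbone_tail(self, rng):
        excess = sppfcspc_params(512, 512) - sppf_params(512)
        assert round(excess / 1e6, 1) == 6.4
        assert SPPFCSPC(512, 512, c_hidden=512, rng=rng).num_parameters() == \
            sppfcspc_params(512, 512)
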