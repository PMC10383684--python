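"""Image-enhancement pipeline: arithmetic, invariants, entropy scoring."""

import numpy as np
import pytest

from teadetect import enhance as E
from teadetect.data import SynthConfig, synth_scene


def _img(arr):
    return np.asarray(arr, dtype=np.uint8)


class TestBrightness:
    def test_identity_scale_and_clipping(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        assert np.array_equal(E.adjust_brightness(img, 1.0), img)
        one = _img(np.full((1, 1, 3), 100))
        assert E.adjust_brightness(one, 1.5)[0, 0, 0] == 150
        two = _img(np.full((1, 1, 3), 200))
        assert E.adjust_brightness(two, 1.5)[0, 0, 0] == 255

    def test_rejects_non_positive_factor(self):
        with pytest.raises(ValueError):
            E.adjust_brightness(np.zeros((2, 2, 3), np.uint8), 0.0)


class TestMirror:
    def test_involution_and_pixel_map(self, rng):
        img = rng.integers(0, 256, (5, 7, 3)).astype(np.uint8)
        for axis in ("horizontal", "vertical"):
            assert np.array_equal(E.mirror_flip(E.mirror_flip(img, axis), axis), img)
        row = _img([[[1] * 3, [2] * 3]])  # 1x2 image [a, b]
        assert np.array_equal(E.mirror_flip(row, "horizontal"), row[:, ::-1])
        sym = _img(np.tile([[3, 9, 3]], (4, 1))[..., None].repeat(3, -1))
        assert np.array_equal(E.mirror_flip(sym, "horizontal"), sym)

    def test_unknown_axis(self):
        with pytest.raises(ValueError):
            E.mirror_flip(np.zeros((2, 2, 3), np.uint8), "diagonal")


class TestHistogramEqualization:
    def test_cumulative_mapping_four_pixel_plane(self):
        # S_0 = 3/4 -> round(0.75 * 255) = 191; top level stays 255
        plane = np.array([0, 0, 0, 255], dtype=np.uint8)
        out = E.equalize_plane(plane)
        assert out.tolist() == [191, 191, 191, 255]

    def test_constant_image_stays_constant(self):
        img = _img(np.full((6, 6, 3), 77))
        out = E.hist_equalize_luma(img)
        assert len(np.unique(out.reshape(-1, 3), axis=0)) == 1

    def test_mapping_monotone(self, rng):
        plane = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        counts = np.bincount(plane.ravel(), minlength=256)
        mapping = np.round(np.cumsum(counts) / plane.size * 255)
        assert np.all(np.diff(mapping) >= 0)

    def test_chroma_untouched(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        before = E.rgb_to_ycbcr(img)[..., 1:]
        after = E.rgb_to_ycbcr(E.hist_equalize_luma(img).astype(np.float64))[..., 1:]
        # chroma survives the RGB round trip up to quantization
        assert np.abs(before - after).mean() < 2.5


class TestGamma:
    @pytest.mark.parametrize(
        "x, gamma, c, expected",
        [(0.0, 2.0, 1.3, 0.0), (0.5, 2.0, 1.0, 0.25), (0.5, 1.0, 1.3, 0.65)],
    )
    def test_normalized_power_law(self, x, gamma, c, expected):
        img = _img(np.full((1, 1, 3), round(x * 255)))
        out = E.gamma_transform(img, gamma, c)[0, 0, 0] / 255.0
        assert out == pytest.approx(expected, abs=1 / 255)

    def test_monotone_in_input(self):
        ramp = _img(np.arange(256)[None, :, None].repeat(3, -1))
        out = E.gamma_transform(ramp, 2.2)
        assert np.all(np.diff(out[0, :, 0].astype(int)) >= 0)

    def test_rejects_bad_gamma(self):
        with pytest.raises(ValueError):
            E.gamma_transform(np.zeros((2, 2, 3), np.uint8), -1.0)


class TestHomomorphicTransfer:
    def test_limits_and_derived_value(self):
        p = E.HomomorphicParams(0.5, 2.0, 1.0, 30.0)
        assert E.homomorphic_transfer(0.0, p) == pytest.approx(0.5)
        assert E.homomorphic_transfer(1e6, p) == pytest.approx(2.0, abs=1e-9)
        # D = D0: (gh-gl)(1 - 1/e) + gl
        assert E.homomorphic_transfer(30.0, p) == pytest.approx(
            1.5 * (1 - np.exp(-1)) + 0.5, abs=1e-12
        )

    def test_bounded_and_monotone_on_grid(self):
        p = E.HomomorphicParams(0.3, 1.8, 2.0, 12.0)
        d = np.linspace(0, 400, 2001)
        h = E.homomorphic_transfer(d, p)
        direct = (1.8 - 0.3) * (1 - np.exp(-2.0 * d**2 / 144)) + 0.3
        assert np.allclose(h, direct, atol=1e-12)
        assert np.all(h >= 0.3) and np.all(h <= 1.8)
        # strictly below the high gain wherever the exponential has not
        # underflowed to zero
        assert np.all(h[d < 50] < 1.8)
        assert np.all(np.diff(h) >= 0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            E.HomomorphicParams(gamma_low=1.2, gamma_high=2.0)


class TestHomomorphicFilter:
    def test_constant_image_stays_constant(self):
        img = _img(np.full((16, 16, 3), 120))
        out = E.homomorphic_filter(img)
        assert len(np.unique(out)) == 1

    def test_identity_transfer_up_to_rescale(self, rng):
        img = rng.integers(30, 220, (32, 32, 3)).astype(np.uint8)
        # degenerate gains both ~1: H ~ 1 everywhere
        p = E.HomomorphicParams(1 - 1e-9, 1 + 1e-9, 1.0, 10.0)
        out = E.homomorphic_filter(img, p).astype(np.float64)
        for ch in range(3):
            a, b = img[..., ch].astype(np.float64), out[..., ch]
            a = (a - a.min()) / (a.max() - a.min())
            b = (b - b.min()) / (b.max() - b.min())
            assert np.abs(a - b).max() < 0.02

    def test_attenuates_illumination_ramp_relative_to_texture(self):
        h = w = 64
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = 80 + 120 * xx / w                      # low-frequency field
        texture = 25 * np.cos(2 * np.pi * xx / 4)     # high-frequency detail
        img = np.clip(ramp + texture, 0, 255)[..., None].repeat(3, -1).astype(np.uint8)
        out = E.homomorphic_filter(img, E.HomomorphicParams(0.4, 2.0, 1.0, 10.0))

        def band_ratio(plane):
            spec = np.abs(np.fft.fftshift(np.fft.fft2(plane - plane.mean())))
            d = np.hypot(*np.mgrid[0:h, 0:w] - np.array([h // 2, w // 2])[:, None, None])
            low = spec[(d > 0) & (d <= 3)].sum()
            high = spec[d > 10].sum()
            return low / high

        assert band_ratio(out[..., 0].astype(float)) < band_ratio(img[..., 0].astype(float))

    def test_rejects_single_pixel(self):
        with pytest.raises(ValueError):
            E.homomorphic_filter(np.zeros((1, 1, 3), np.uint8))


class TestLocalHomomorphic:
    def test_single_block_equals_global(self, small_scene):
        img = small_scene.image[:64, :64]
        p = E.HomomorphicParams()
        assert np.array_equal(
            E.local_homomorphic_filter(img, 1, p), E.homomorphic_filter(img, p)
        )

    def test_tiling_preserves_shape(self, small_scene):
        out = E.local_homomorphic_filter(small_scene.image[:100, :100], 2)
        assert out.shape == (100, 100, 3)
        assert out.dtype == np.uint8

    def test_grid_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            E.local_homomorphic_filter(np.zeros((4, 4, 3), np.uint8), 9)


class TestEntropy:
    def test_degenerate_histograms(self):
        assert E.shannon_entropy_gray(np.full((8, 8), 7)) == 0.0
        half = np.array([0] * 32 + [255] * 32).reshape(8, 8)
        assert E.shannon_entropy_gray(half) == pytest.approx(1.0)
        uniform = np.arange(256).reshape(16, 16)
        assert E.shannon_entropy_gray(uniform) == pytest.approx(8.0)

    def test_matches_probability_sum_oracle(self, rng):
        for _ in range(10):
            plane = rng.integers(0, 256, (16, 16))
            # brute-force: probability of each distinct value
            vals, counts = np.unique(plane, return_counts=True)
            p = counts / plane.size
            oracle = -(p * np.log2(p)).sum()
            assert E.shannon_entropy_gray(plane) == pytest.approx(oracle, abs=1e-12)

    def test_empty_plane_rejected(self):
        with pytest.raises(ValueError):
            E.shannon_entropy_gray(np.zeros((0, 4)))

    def test_local_average_entropy_reductions(self, small_scene):
        img = small_scene.image
        rep = E.local_average_entropy(img, 4)
        assert rep.local_average_entropy == pytest.approx(
            float(np.mean(rep.per_channel))
        )
        const = np.full((32, 32, 3), 9, np.uint8)
        assert E.local_average_entropy(const, 4).local_average_entropy == 0.0
        # single block = global entropy per channel
        rep1 = E.local_average_entropy(img, 1)
        assert rep1.per_channel[0] == pytest.approx(
            E.shannon_entropy_gray(img[..., 0])
        )
        # gray image: color value equals the channel value
        gray = np.repeat(img[..., :1], 3, axis=2)
        repg = E.local_average_entropy(gray, 4)
        assert repg.local_average_entropy == pytest.approx(repg.per_channel[0])


class TestTableOrdering:
    def test_local_filtering_raises_entropy_global_lowers_it(self):
        """Strong illumination gradient: local > original > global."""
        scene = synth_scene(SynthConfig(image_size=320, seed=42))
        p = E.HomomorphicParams()
        e_orig = E.local_average_entropy(scene.image, 8).local_average_entropy
        e_glob = E.local_average_entropy(
            E.homomorphic_filter(scene.image, p), 8
        ).local_average_entropy
        e_loc = E.local_average_entropy(
            E.local_homomorphic_filter(scene.image, 8, p), 8
        ).local_average_entropy
        assert e_loc > e_orig > e_glob


class TestShapeRangeContract:
    def test_every_op_preserves_dtype_range_shape(self, small_scene):
        img = small_scene.image[:64, :64]
        p = E.HomomorphicParams()
        outputs = [
            E.adjust_brightness(img, 1.4),
            E.mirror_flip(img, "vertical"),
            E.hist_equalize_luma(img),
            E.gamma_transform(img, 0.7),
            E.homomorphic_filter(img, p),
            E.local_homomorphic_filter(img, 4, p),
        ]
        for out in outputs:
            assert out.shape == img.shape
            assert out.dtype == np.uint8
            assert out.min() >= 0 and out.max() <= 255
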