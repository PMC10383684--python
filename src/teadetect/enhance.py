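"""Classical image enhancement and entropy-based quality scoring.

The dataset-expansion pipeline: brightness scaling, mirror flips, luminance
histogram equalization (YCbCr, BT.601 full range), gamma correction
y = c * x^gamma on [0, 1]-normalized intensities, and homomorphic filtering
— globally or per sub-image on an n x n grid.

Homomorphic filtering separates illumination from reflectance by filtering
the log-image in the frequency domain with a Gaussian high-pass transfer

    H(u, v) = (gamma_high - gamma_low) * (1 - exp(-c D^2 / D0^2)) + gamma_low

which attenuates the smooth illumination field (low frequencies, gain ->
gamma_low < 1) and boosts reflectance detail (high frequencies, gain ->
gamma_high > 1).  Image quality is scored by local average entropy: the
Shannon entropy of the 256-level histogram, averaged over the grid blocks
and over the R, G, B channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HomomorphicParams",
    "EntropyReport",
    "adjust_brightness",
    "mirror_flip",
    "hist_equalize_luma",
    "gamma_transform",
    "homomorphic_transfer",
    "homomorphic_filter",
    "local_homomorphic_filter",
    "shannon_entropy_gray",
    "local_average_entropy",
]

L_LEVELS = 256


@dataclass
class HomomorphicParams:
    gamma_low: float = 0.5
    gamma_high: float = 2.0
    c_slope: float = 1.0
    d0: float = 30.0  # cutoff frequency, cycles

    def __post_init__(self):
        if not (self.gamma_low < 1.0 < self.gamma_high):
            raise ValueError("need gamma_low < 1 < gamma_high")
        if self.d0 <= 0 or self.c_slope <= 0:
            raise ValueError("d0 and c_slope must be positive")


@dataclass
class EntropyReport:
    block_grid: tuple          # (rows, cols)
    per_block_entropy: np.ndarray  # (rows, cols) mean over channels, bits
    local_average_entropy: float   # bits
    per_channel: tuple             # (R, G, B) local average entropies


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("expected an HxWx3 image")
    return img


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Scale every channel by ``factor`` and clip to [0, 255]."""
    img = _check_image(img)
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    return np.clip(img.astype(np.float64) * factor, 0, 255).round().astype(np.uint8)


def mirror_flip(img: np.ndarray, axis: str = "horizontal") -> np.ndarray:
    img = _check_image(img)
    if axis == "horizontal":
        return img[:, ::-1].copy()
    if axis == "vertical":
        return img[::-1].copy()
    raise ValueError("axis must be 'horizontal' or 'vertical'")


# BT.601 full-range RGB <-> YCbCr
def rgb_to_ycbcr(img: np.ndarray) -> np.ndarray:
    r, g, b = (img[..., i].astype(np.float64) for i in range(3))
    y = 0.299 * r + 0.587 * g + 0.114 * b
    cb = 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b
    cr = 128.0 + 0.5 * r - 0.418688 * g - 0.081312 * b
    return np.stack([y, cb, cr], axis=-1)


def ycbcr_to_rgb(ycc: np.ndarray) -> np.ndarray:
    y, cb, cr = (ycc[..., i] for i in range(3))
    r = y + 1.402 * (cr - 128.0)
    g = y - 0.344136 * (cb - 128.0) - 0.714136 * (cr - 128.0)
    b = y + 1.772 * (cb - 128.0)
    return np.clip(np.stack([r, g, b], axis=-1), 0, 255)


def equalize_plane(plane: np.ndarray) -> np.ndarray:
    """Histogram-equalize one 8-bit plane: k -> round(S_k * (L-1))."""
    counts = np.bincount(plane.ravel(), minlength=L_LEVELS)
    cdf = np.cumsum(counts) / plane.size
    mapping = np.round(cdf * (L_LEVELS - 1)).astype(np.uint8)
    return mapping[plane]


def hist_equalize_luma(img: np.ndarray) -> np.ndarray:
    """Equalize the Y plane in YCbCr; chroma untouched."""
    img = _check_image(img)
    ycc = rgb_to_ycbcr(img)
    y8 = np.clip(np.round(ycc[..., 0]), 0, 255).astype(np.uint8)
    ycc[..., 0] = equalize_plane(y8)
    return ycbcr_to_rgb(ycc).round().astype(np.uint8)


def gamma_transform(img: np.ndarray, gamma: float, c_scale: float = 1.3) -> np.ndarray:
    """Power-law correction y = c x^gamma on [0, 1] intensities, clipped."""
    img = _check_image(img)
    if gamma <= 0 or c_scale <= 0:
        raise ValueError("gamma and c_scale must be positive")
    x = img.astype(np.float64) / 255.0
    y = np.clip(c_scale * x**gamma, 0.0, 1.0)
    return np.round(y * 255.0).astype(np.uint8)


def homomorphic_transfer(u_dist, p: HomomorphicParams):
    """Gaussian high-pass gain H(D) in [gamma_low, gamma_high)."""
    d2 = np.asarray(u_dist, dtype=np.float64) ** 2
    h = (p.gamma_high - p.gamma_low) * (
        1.0 - np.exp(-p.c_slope * d2 / p.d0**2)
    ) + p.gamma_low
    return float(h) if h.ndim == 0 else h


def _filter_plane(plane: np.ndarray, p: HomomorphicParams) -> np.ndarray:
    """log -> centered FFT -> H(u,v) -> inverse FFT -> expm1 (unscaled)."""
    h, w = plane.shape
    logged = np.log1p(plane.astype(np.float64))
    spec = np.fft.fftshift(np.fft.fft2(logged))
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - h // 2, xx - w // 2)
    spec *= homomorphic_transfer(d, p)
    back = np.real(np.fft.ifft2(np.fft.ifftshift(spec)))
    return np.expm1(back)


def _rescale_plane(plane: np.ndarray) -> np.ndarray:
    lo, hi = plane.min(), plane.max()
    if hi - lo < 1e-9:
        return np.clip(np.round(plane), 0, 255).astype(np.uint8)
    return np.round((plane - lo) / (hi - lo) * 255.0).astype(np.uint8)


def homomorphic_filter(img: np.ndarray, p: HomomorphicParams | None = None) -> np.ndarray:
    """Global homomorphic filtering, per channel, min-max rescaled."""
    img = _check_image(img)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    p = p or HomomorphicParams()
    out = np.empty_like(img)
    for ch in range(3):
        out[..., ch] = _rescale_plane(_filter_plane(img[..., ch], p))
    return out


def _grid_blocks(h: int, w: int, n: int):
    """n x n contiguous blocks; the last row/column absorbs the remainder."""
    hs = [h // n] * n
    ws = [w // n] * n
    hs[-1] += h - sum(hs)
    ws[-1] += w - sum(ws)
    y = 0
    for bh in hs:
        x = 0
        for bw in ws:
            yield slice(y, y + bh), slice(x, x + bw)
            x += bw
        y += bh


def local_homomorphic_filter(img: np.ndarray, grid: int | tuple = 8,
                             p: HomomorphicParams | None = None) -> np.ndarray:
    """Homomorphic filtering applied independently per grid block."""
    img = _check_image(img)
    n = grid[0] if isinstance(grid, (tuple, list)) else int(grid)
    h, w = img.shape[:2]
    if n < 1 or n > min(h, w):
        raise ValueError("grid must satisfy 1 <= n <= min(H, W)")
    p = p or HomomorphicParams()
    out = np.empty_like(img)
    for ys, xs in _grid_blocks(h, w, n):
        out[ys, xs] = homomorphic_filter(img[ys, xs], p)
    return out


def shannon_entropy_gray(plane: np.ndarray) -> float:
    """Entropy (bits) of the 256-bin histogram of an 8-bit plane."""
    plane = np.asarray(plane)
    if plane.size == 0:
        raise ValueError("empty plane")
    if plane.min() < 0 or plane.max() > 255:
        raise ValueError("plane values must lie in [0, 255]")
    counts = np.bincount(plane.astype(np.int64).ravel(), minlength=L_LEVELS)
    probs = counts[counts > 0] / plane.size
    return float(-(probs * np.log2(probs)).sum())


def local_average_entropy(img: np.ndarray, grid: int | tuple = 8) -> EntropyReport:
    """Mean per-block entropy per channel; color value = channel mean."""
    img = _check_image(img)
    n = grid[0] if isinstance(grid, (tuple, list)) else int(grid)
    h, w = img.shape[:2]
    if n < 1 or n > min(h, w):
        raise ValueError("grid must satisfy 1 <= n <= min(H, W)")
    per_block = np.zeros((n, n, 3))
    for i, (ys, xs) in enumerate(_grid_blocks(h, w, n)):
        r, c = divmod(i, n)
        for ch in range(3):
            per_block[r, c, ch] = shannon_entropy_gray(img[ys, xs, ch])
    per_channel = tuple(per_block[..., ch].mean() for ch in range(3))
    return EntropyReport(
        block_grid=(n, n),
        per_block_entropy=per_block.mean(axis=2),
        local_average_entropy=float(np.mean(per_channel)),
        per_channel=per_channel,
    )
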