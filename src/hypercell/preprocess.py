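"""Quality control and normalization of 8-bit microscopy images.

The screening pipeline drops over-bright fields (mean brightness above 240 on
the 0-255 HSV value scale, where cell boundaries wash out into background),
rescales the survivors to a common mean brightness of ~130, and resizes them
to a fixed 220 x 300 raster.  Separate operators cover the classic cleanup
steps used when building the spatial-spectral representation: median
denoising, histogram equalization and linear/gamma contrast adjustment.

All operators are deterministic and defined on plain arrays so they can be
checked against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HSVStats",
    "compute_hsv_stats",
    "exclude_by_brightness",
    "normalize_mean_v",
    "resize_image",
    "median_denoise",
    "equalize_histogram",
    "adjust_contrast",
    "preprocess_set",
]


@dataclass(frozen=True)
class HSVStats:
    """Channel means of an image in HSV space, each on the 0-255 scale."""

    mean_h: float
    mean_s: float
    mean_v: float

    def __post_init__(self) -> None:
        for name in ("mean_h", "mean_s", "mean_v"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name}={v} outside [0, 255]")


def compute_hsv_stats(image: np.ndarray) -> HSVStats:
    """Mean H, S and V of an 8-bit grayscale or RGB image.

    A grayscale image is treated as pure value: V is the pixel intensity and
    H = S = 0.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 2:
        return HSVStats(0.0, 0.0, float(image.mean()))
    if image.ndim == 3 and image.shape[2] == 3:
        from skimage.color import rgb2hsv

        hsv = rgb2hsv(image) * 255.0
        return HSVStats(*(float(hsv[..., k].mean()) for k in range(3)))
    raise ValueError(f"expected 2-D grayscale or H x W x 3 RGB; got {image.shape}")


def exclude_by_brightness(
    images: list[np.ndarray], threshold: float = 240.0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Partition images into (kept, excluded) by mean brightness.

    An image is excluded iff its mean V strictly exceeds ``threshold``; the
    boundary value itself is kept.
    """
    if not (0.0 < threshold <= 255.0):
        raise ValueError(f"threshold must be in (0, 255]; got {threshold}")
    kept: list[np.ndarray] = []
    excluded: list[np.ndarray] = []
    for img in images:
        (excluded if compute_hsv_stats(img).mean_v > threshold else kept).append(img)
    return kept, excluded


def normalize_mean_v(
    image: np.ndarray, target: float = 130.0, tol: float = 1.0, max_iter: int = 5
) -> np.ndarray:
    """Rescale an image so its mean brightness lands within ``tol`` of ``target``.

    Multiplicative rescale with clipping to [0, 255]; because clipping eats
    part of the gain, the scale is re-applied up to ``max_iter`` times until
    the mean settles.  Returns float64.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    out = image
    for _ in range(max_iter):
        mean = out.mean()
        if abs(mean - target) <= tol:
            return out
        if mean == 0.0:
            raise ValueError("all-zero image cannot be rescaled to a nonzero target")
        out = np.clip(out * (target / mean), 0.0, 255.0)
    return out


def resize_image(image: np.ndarray, target_hw: tuple[int, int] = (220, 300)) -> np.ndarray:
    """Bilinear resize to ``target_hw`` (height, width).

    Pixel centers are aligned by the half-pixel convention (an output pixel at
    index i samples input coordinate (i + 0.5) * scale - 0.5) with edge
    clamping, so constant images stay exactly constant.
    """
    th, tw = int(target_hw[0]), int(target_hw[1])
    if th < 1 or tw < 1:
        raise ValueError(f"target dims must be >= 1; got {target_hw}")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("resize_image expects a single-channel image")
    h, w = image.shape
    rr = (np.arange(th) + 0.5) * (h / th) - 0.5
    cc = (np.arange(tw) + 0.5) * (w / tw) - 0.5
    grid = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(image, grid, order=1, mode="nearest")


def median_denoise(image: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with a ``kernel x kernel`` window, edge-replicate padding."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3; got {kernel}")
    return ndimage.median_filter(np.asarray(image), size=kernel, mode="nearest")


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Classic 8-bit histogram equalization via the cumulative-distribution map.

    Each gray level v maps to round((cdf(v) - cdf_min) / (N - cdf_min) * 255)
    where N is the pixel count and cdf_min the CDF at the darkest occupied
    level; the mapping is monotone in input rank.  A constant image is
    returned unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("equalize_histogram expects a single-channel image")
    vals = np.clip(image, 0, 255).astype(np.int64)
    counts = np.bincount(vals.ravel(), minlength=256)
    cdf = np.cumsum(counts)
    if vals.size == 0:
        raise ValueError("empty image")
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    n = vals.size
    if n == cdf_min:  # single occupied gray level
        return image.copy()
    lut = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0).astype(image.dtype)
    return lut[vals]


def adjust_contrast(image: np.ndarray, gain: float, mode: str = "linear") -> np.ndarray:
    """Contrast adjustment.

    linear: out = clip(mean + gain * (in - mean), 0, 255) — stretches about
    the image mean; gain 1 is the identity, gain 0 collapses to the mean.
    gamma: out = 255 * (in / 255) ** gain — nonlinear tone curve (gain > 0).
    """
    if gain < 0 or (mode == "gamma" and gain == 0):
        raise ValueError(f"gain must be > 0 ({mode} mode); got {gain}")
    image = np.asarray(image, dtype=np.float64)
    if mode == "linear":
        mean = image.mean()
        return np.clip(mean + gain * (image - mean), 0.0, 255.0)
    if mode == "gamma":
        return 255.0 * (np.clip(image, 0.0, 255.0) / 255.0) ** gain
    raise ValueError(f"mode must be 'linear' or 'gamma'; got {mode!r}")


def preprocess_set(
    images: list[np.ndarray],
    v_threshold: float = 240.0,
    v_target: float = 130.0,
    resize_hw: tuple[int, int] = (220, 300),
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """QC pipeline: brightness exclusion, mean-V normalization, resize.

    Returns (processed kept images, excluded originals); the kept count is
    decided by the exclusion step alone.
    """
    kept, excluded = exclude_by_brightness(images, v_threshold)
    processed = [resize_image(normalize_mean_v(img, v_target), resize_hw) for img in kept]
    return processed, excluded
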