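"""Synthetic labeled hyperspectral cell cubes.

No public dataset of labeled hyperspectral microscopy fields of mesenchymal
stromal cells exists, so every pipeline stage is exercised on generated
cubes that reproduce the statistical structure the classifier consumes:
cell-shaped (elliptical) regions whose classes differ by their mean spectrum,
per-band additive Gaussian noise, and optional spatial blur.  Morphological
realism (the fibroblast-like outline of real cells) is deliberately not
imitated — the classifier is patch-based and only the label/spectrum
structure matters for correctness.

Task difficulty is summarized by spectral separability: the minimum pairwise
Euclidean distance between class signatures divided by the noise standard
deviation.  Zero-noise cubes (infinite separability) are perfectly
classifiable by nearest-signature assignment and serve as the end-to-end
sanity floor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io import HSCube, LabelMask

__all__ = [
    "SynthParams",
    "PlacementError",
    "default_signatures",
    "task_params",
    "generate_cube",
    "generate_grayscale_set",
    "sample_labeled_pixels",
    "spectral_separability",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping cells cannot be placed in the field."""


def default_signatures(bands: int = 8) -> np.ndarray:
    """Per-class mean spectra, shape (3, bands): background, high, low.

    Background is spectrally flat and dim; the two cell classes carry
    opposite spectral ramps so they differ in band shape, not just in
    overall brightness — the situation the spectral classifier is for.
    """
    ramp = np.linspace(60.0, 140.0, bands)
    return np.stack([np.full(bands, 40.0), ramp, ramp[::-1]])


@dataclass
class SynthParams:
    """Generation parameters for one labeled cube.

    ``class_signatures`` has shape (3, bands) in the label order background,
    high-functioning, low-functioning.  ``class_mix`` gives the fraction of
    cells assigned to (high, low) and must sum to 1.  The same seed always
    yields a bitwise-identical cube and mask.
    """

    height: int = 64
    width: int = 64
    bands: int = 8
    n_cells: int = 12
    cell_axes_range: tuple[float, float] = (4.0, 9.0)
    class_signatures: np.ndarray | None = None
    noise_sd: float = 5.0
    blur_sigma: float = 0.0
    class_mix: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_signatures is None:
            self.class_signatures = default_signatures(self.bands)
        self.class_signatures = np.asarray(self.class_signatures, dtype=np.float64)
        if self.class_signatures.shape != (3, self.bands):
            raise ValueError(
                f"class_signatures must be (3, {self.bands}); "
                f"got {self.class_signatures.shape}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0; got {self.noise_sd}")
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ValueError(f"class_mix must sum to 1; got {self.class_mix}")

    def replace(self, **kw) -> "SynthParams":
        return replace(self, **kw)


#: Target separability per difficulty preset; "easy" clears the >= 10
#: threshold with margin, "hard" sits at <= 2 where single spectra are
#: unreliable and spatial pooling / extra samples are what help.
_TASK_SEPARABILITY = {"easy": 20.0, "medium": 4.0, "hard": 1.5}


def task_params(difficulty: str, seed: int = 0, **overrides) -> SynthParams:
    """Preset parameters for an easy / medium / hard classification task.

    The noise level is set from the default signatures so that
    ``spectral_separability`` equals the preset target exactly.
    """
    if difficulty not in _TASK_SEPARABILITY:
        raise ValueError(f"difficulty must be one of {sorted(_TASK_SEPARABILITY)}")
    base = SynthParams(seed=seed, **{k: v for k, v in overrides.items() if k != "noise_sd"})
    sig = base.class_signatures
    dmin = min(
        float(np.linalg.norm(sig[i] - sig[j]))
        for i in range(3)
        for j in range(i + 1, 3)
    )
    return base.replace(noise_sd=dmin / _TASK_SEPARABILITY[difficulty])


def _place_cells(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Rasterize non-overlapping ellipses; returns the H x W label mask."""
    h, w = params.height, params.width
    labels = np.zeros((h, w), dtype=np.int64)
    occupied = np.zeros((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    lo, hi = params.cell_axes_range
    max_tries = 500 * max(params.n_cells, 1)
    placed = 0
    tries = 0
    while placed < params.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {placed}/{params.n_cells} non-overlapping cells "
                f"in {tries} attempts on a {h}x{w} field"
            )
        tries += 1
        a = rng.uniform(lo, hi)
        b = rng.uniform(lo, hi)
        theta = rng.uniform(0.0, np.pi)
        cr = rng.uniform(a, h - a)
        cx = rng.uniform(b, w - b)
        ct, st = np.cos(theta), np.sin(theta)
        u = (rr - cr) * ct + (cc - cx) * st
        v = -(rr - cr) * st + (cc - cx) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not inside.any() or (inside & occupied).any():
            continue
        klass = 1 if rng.random() < params.class_mix[0] else 2
        labels[inside] = klass
        occupied |= inside
        placed += 1
    return labels


def generate_cube(params: SynthParams) -> tuple[HSCube, LabelMask]:
    """Generate one labeled cube.

    Each pixel's spectrum is its class signature plus i.i.d. N(0, noise_sd^2)
    per band; when ``blur_sigma`` > 0 each band is then Gaussian-blurred
    spatially (blurring signal and noise together, as optics would).
    """
    rng = np.random.default_rng(params.seed)
    labels = _place_cells(params, rng)
    data = params.class_signatures[labels]
    if params.noise_sd > 0:
        data = data + rng.normal(0.0, params.noise_sd, size=data.shape)
    if params.blur_sigma > 0:
        data = ndimage.gaussian_filter(
            data, sigma=(params.blur_sigma, params.blur_sigma, 0.0)
        )
    cube = HSCube(data, name=f"synthetic-seed{params.seed}")
    return cube, LabelMask(labels)


def generate_grayscale_set(
    n: int, brightness_spec, seed: int = 0
) -> list[np.ndarray]:
    """Generate ``n`` grayscale images (0-255 scale) with exact mean brightness.

    ``brightness_spec`` is either one target mean or a length-``n`` sequence
    of per-image targets.  Noise is centered after sampling so each image's
    mean equals its target exactly, which makes brightness-threshold tests
    sharp.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0; got {n}")
    targets = np.broadcast_to(np.asarray(brightness_spec, dtype=np.float64), (n,))
    rng = np.random.default_rng(seed)
    images = []
    for t in targets:
        if not (0.0 <= t <= 255.0):
            raise ValueError(f"target mean {t} outside [0, 255]")
        amp = min(4.0, t, 255.0 - t)
        noise = rng.uniform(-amp, amp, size=(32, 32))
        noise -= noise.mean()
        images.append(np.full((32, 32), t) + noise)
    return images


def sample_labeled_pixels(
    mask: LabelMask,
    per_class: int,
    seed: int = 0,
    classes: tuple[int, ...] = (0, 1, 2),
) -> list[tuple[int, int, int]]:
    """Draw up to ``per_class`` random (row, col, label) triples per class."""
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int, int]] = []
    for klass in classes:
        rows, cols = np.nonzero(mask.labels == klass)
        if rows.size == 0:
            continue
        take = min(per_class, rows.size)
        idx = rng.choice(rows.size, size=take, replace=False)
        out.extend((int(rows[i]), int(cols[i]), int(klass)) for i in idx)
    return out


def spectral_separability(params: SynthParams) -> float:
    """Minimum pairwise signature distance over noise SD; inf when noiseless.

    Tasks with separability >= 10 are "easy" (single spectra suffice);
    <= 2 is "hard" (spatial context and sample count dominate).
    """
    sig = np.asarray(params.class_signatures, dtype=np.float64)
    if sig.shape[0] < 2:
        raise ValueError("separability needs at least 2 classes")
    dists = [
        float(np.linalg.norm(sig[i] - sig[j]))
        for i in range(sig.shape[0])
        for j in range(i + 1, sig.shape[0])
    ]
    dmin = min(dists)
    if params.noise_sd == 0:
        return float("inf")
    return dmin / params.noise_sd
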