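"""Spatial-spectral combined distance (SSCD) and neighbor augmentation.

Pixels that are close in space tend to share a class, so the spectra in a
pixel's square spatial window carry information about the pixel itself.  The
SSCD between two pixels is defined here as the Euclidean distance between
the spatially averaged spectra of their windows; at window size 1 it reduces
to plain spectral distance.  For each labeled pixel, its k nearest in-window
neighbors under SSCD (its spatial-spectral neighbors, SSNs) are grafted onto
the training set with the labeled pixel's class — a cheap augmentation that
multiplies scarce ground-truth labels.

Coordinates are row-major and 0-based; windows are edge-replicated at cube
borders, and all neighbor orderings break ties by row-major position so
results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from logging import getLogger

import numpy as np

from .io import HSCube

__all__ = [
    "WindowPatch",
    "SSNSet",
    "PixelSample",
    "extract_window",
    "sscd_distance",
    "select_ssn",
    "make_pixel_samples",
    "augment_training_set",
]

logger = getLogger("hypercell")


@dataclass
class WindowPatch:
    """A ws x ws x B spatial window of spectra centered on one pixel."""

    center: tuple[int, int]
    data: np.ndarray
    ws: int
    padding: str = "edge"

    def __post_init__(self) -> None:
        if self.ws % 2 == 0 or self.ws < 1:
            raise ValueError(f"ws must be odd and >= 1; got {self.ws}")
        if self.data.shape[:2] != (self.ws, self.ws):
            raise ValueError(
                f"patch spatial shape {self.data.shape[:2]} != ({self.ws}, {self.ws})"
            )

    @property
    def mean_spectrum(self) -> np.ndarray:
        """Spectrum averaged over the spatial window; length B."""
        return self.data.mean(axis=(0, 1))


@dataclass
class SSNSet:
    """The k nearest spatial-spectral neighbors of one pixel.

    ``neighbors`` is sorted ascending by distance, ties broken by row-major
    position; the center pixel never lists itself.
    """

    center: tuple[int, int]
    neighbors: list[tuple[tuple[int, int], float]]
    k: int

    def __post_init__(self) -> None:
        if len(self.neighbors) > self.k:
            raise ValueError("more neighbors than k")
        if any(pos == self.center for pos, _ in self.neighbors):
            raise ValueError("center cannot be its own neighbor")

    def positions(self) -> list[tuple[int, int]]:
        return [pos for pos, _ in self.neighbors]


@dataclass
class PixelSample:
    """One (possibly augmented) training sample: a pixel with patch and label."""

    position: tuple[int, int]
    spectrum: np.ndarray
    patch: WindowPatch
    label: int
    provenance: str = "original"
    source: tuple[int, int] | None = None
    distance: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be in {{0, 1, 2}}; got {self.label}")
        if self.provenance not in ("original", "ssn-augmented"):
            raise ValueError(f"bad provenance {self.provenance!r}")


def extract_window(cube: HSCube, center: tuple[int, int], ws: int) -> WindowPatch:
    """Extract the ws x ws window around ``center``, replicating edges."""
    if ws % 2 == 0 or ws < 1:
        raise ValueError(f"ws must be odd and >= 1; got {ws}")
    h, w, _ = cube.shape
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise IndexError(f"center {center} outside {h}x{w} cube")
    half = ws // 2
    rows = np.clip(np.arange(r - half, r + half + 1), 0, h - 1)
    cols = np.clip(np.arange(c - half, c + half + 1), 0, w - 1)
    return WindowPatch(center=(r, c), data=cube.data[np.ix_(rows, cols)], ws=ws)


def sscd_distance(a: WindowPatch, b: WindowPatch) -> float:
    """Euclidean distance between the window-averaged spectra of two patches."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"patch shapes differ: {a.data.shape} vs {b.data.shape}")
    return float(np.linalg.norm(a.mean_spectrum - b.mean_spectrum))


def select_ssn(cube: HSCube, center: tuple[int, int], ws: int, k: int) -> SSNSet:
    """Pick the k in-window candidates nearest to ``center`` under SSCD.

    The candidate pool is the in-bounds part of the ws x ws window around the
    center, minus the center itself; when the pool holds fewer than k pixels
    all of them are returned.  Each candidate is compared through its own
    ws x ws window, so the ranking uses joint spatial-spectral similarity.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0; got {k}")
    h, w, _ = cube.shape
    r, c = center
    center_patch = extract_window(cube, center, ws)
    half = ws // 2
    scored: list[tuple[float, tuple[int, int]]] = []
    for rr in range(max(0, r - half), min(h, r + half + 1)):
        for cc in range(max(0, c - half), min(w, c + half + 1)):
            if (rr, cc) == (r, c):
                continue
            d = sscd_distance(center_patch, extract_window(cube, (rr, cc), ws))
            scored.append((d, (rr, cc)))
    scored.sort(key=lambda t: (t[0], t[1]))
    top = scored[: min(k, len(scored))]
    return SSNSet(center=(r, c), neighbors=[(pos, d) for d, pos in top], k=k)


def make_pixel_samples(
    cube: HSCube, labeled: list[tuple[int, int, int]], ws: int
) -> list[PixelSample]:
    """Wrap sparse (row, col, label) triples into PixelSample objects."""
    out = []
    for r, c, label in labeled:
        patch = extract_window(cube, (r, c), ws)
        out.append(
            PixelSample(
                position=(r, c),
                spectrum=cube.data[r, c].copy(),
                patch=patch,
                label=int(label),
            )
        )
    return out


def augment_training_set(
    cube: HSCube, labeled: list[PixelSample], ws: int, k: int
) -> list[PixelSample]:
    """Enlarge a labeled sample set with each sample's k SSNs.

    Augmented samples inherit their source pixel's label.  When several
    sources claim the same position (or an augmented position coincides with
    an original), the smallest-distance assignment wins — originals carry
    distance 0 and therefore always prevail.  Output size is at most
    n * (k + 1).
    """
    best: dict[tuple[int, int], PixelSample] = {}
    order: list[tuple[int, int]] = []
    for sample in labeled:
        pos = sample.position
        if pos not in best:
            order.append(pos)
            best[pos] = sample
        elif sample.distance < best[pos].distance:
            best[pos] = sample
    for sample in labeled:
        ssn = select_ssn(cube, sample.position, ws, k)
        for pos, dist in ssn.neighbors:
            candidate = PixelSample(
                position=pos,
                spectrum=cube.data[pos].copy(),
                patch=extract_window(cube, pos, ws),
                label=sample.label,
                provenance="ssn-augmented",
                source=sample.position,
                distance=dist,
            )
            if pos not in best:
                order.append(pos)
                best[pos] = candidate
            elif dist < best[pos].distance:
                if best[pos].label != candidate.label:
                    logger.debug(
                        "augmentation conflict at %s: label %d (d=%.4g) replaces "
                        "%d (d=%.4g)", pos, candidate.label, dist,
                        best[pos].label, best[pos].distance,
                    )
                best[pos] = candidate
    return [best[pos] for pos in order]
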