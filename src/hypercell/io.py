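"""Readers and writers for hyperspectral cubes, label masks, configs and reports.

Cubes travel either as ENVI header+raw pairs (the de-facto interchange format
for hyperspectral imagery) or as numpy ``.npz`` archives, which keep test
fixtures dependency-light.  The band axis is always last in memory: a cube is
an ``H x W x B`` array whose ``[r, c, :]`` slice is the spectrum of one pixel.

Label masks are ordinary 8-bit images (PNG or TIFF) with the fixed coding
0 = background, 1 = high-functioning, 2 = low-functioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "HSCube",
    "LabelMask",
    "PipelineConfig",
    "CLASS_NAMES",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "write_metrics_report",
    "read_metrics_report",
    "setup_logging",
]

logger = logging.getLogger("hypercell")

#: Fixed class coding; colors in figures are display-only.
CLASS_NAMES = ("background", "high", "low")


def setup_logging(level: int | str = logging.INFO) -> logging.Logger:
    """Configure the package logger with a plain-text stream handler."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


@dataclass
class HSCube:
    """A hyperspectral image cube.

    Parameters
    ----------
    data:
        ``H x W x B`` array of non-negative intensities (arbitrary units).
    wavelengths:
        Optional band-center wavelengths in nm, length ``B``.
    name:
        Free-text identifier carried through result files.
    """

    data: np.ndarray
    wavelengths: list[float] | None = None
    name: str = "cube"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"cube data must have exactly 3 axes (H, W, B); got {self.data.ndim}"
            )
        h, w, b = self.data.shape
        if h < 1 or w < 1 or b < 1:
            raise ValueError(f"cube dims must all be >= 1; got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if self.wavelengths is not None:
            self.wavelengths = [float(x) for x in self.wavelengths]
            if len(self.wavelengths) != b:
                raise ValueError(
                    f"{len(self.wavelengths)} wavelengths for {b} bands"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def band_count(self) -> int:
        return self.data.shape[2]


@dataclass
class LabelMask:
    """Integer class map paired with a cube; values in {0, 1, 2}."""

    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D; got {self.labels.ndim} axes")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"mask dtype must be integer; got {self.labels.dtype}")
        bad = np.setdiff1d(np.unique(self.labels), np.arange(len(self.class_names)))
        if bad.size:
            raise ValueError(
                f"mask contains out-of-range label value(s) {bad.tolist()}; "
                f"allowed: 0..{len(self.class_names) - 1}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, echoed into all result artifacts.

    ``ws`` is the (odd) side length of the square spatial window used both for
    neighbor selection and as the classifier's input patch; ``k_ssn`` is the
    number of spatial-spectral neighbors grafted onto each labeled pixel.
    """

    ws: int = 9
    k_ssn: int = 12
    v_exclude_threshold: float = 240.0
    v_target: float = 130.0
    resize_hw: tuple[int, int] = (220, 300)
    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0
    block_channels: tuple[int, ...] = (16, 32)
    kernel: int = 3

    def __post_init__(self) -> None:
        if self.ws < 1 or self.ws % 2 == 0:
            raise ValueError(f"ws must be odd and >= 1; got {self.ws}")
        if self.k_ssn < 0:
            raise ValueError(f"k_ssn must be >= 0; got {self.k_ssn}")
        self.resize_hw = tuple(int(x) for x in self.resize_hw)
        self.block_channels = tuple(int(x) for x in self.block_channels)

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resize_hw"] = list(self.resize_hw)
        d["block_channels"] = list(self.block_channels)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)


# --------------------------------------------------------------------------
# ENVI header + raw
# --------------------------------------------------------------------------

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if val.startswith("{") and not val.endswith("}"):
                buf = val
                continue
            fields[key] = val.strip("{}").strip()
            key = None
        else:
            buf += " " + line
            if line.endswith("}"):
                fields[key] = buf.strip("{}").strip()
                key = None
                buf = ""
    return fields


def _read_envi(hdr_path: Path) -> HSCube:
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as exc:
        raise ValueError(f"ENVI header {hdr_path} missing field {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():
        raw_path = hdr_path.with_suffix(".img")
    if not raw_path.exists():
        raise FileNotFoundError(f"no .raw/.img companion for {hdr_path}")
    flat = np.fromfile(raw_path, dtype=dtype)
    expected = lines * samples * bands
    if flat.size != expected:
        raise ValueError(
            f"{raw_path}: {flat.size} values, header implies {expected}"
        )
    if interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wav = None
    if "wavelength" in fields:
        wav = [float(x) for x in fields["wavelength"].split(",") if x.strip()]
    return HSCube(np.ascontiguousarray(data), wavelengths=wav, name=hdr_path.stem)


def _write_envi(cube: HSCube, hdr_path: Path) -> None:
    data = cube.data
    if data.dtype not in _ENVI_CODES:
        data = data.astype(np.float64)
    code = _ENVI_CODES[np.dtype(data.dtype)]
    h, w, b = data.shape
    lines = [
        "ENVI",
        f"description = {{{cube.name}}}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bip",
        "byte order = 0",
    ]
    if cube.wavelengths is not None:
        lines.append("wavelength = {" + ", ".join(f"{x:g}" for x in cube.wavelengths) + "}")
    hdr_path.write_text("\n".join(lines) + "\n")
    np.ascontiguousarray(data).tofile(hdr_path.with_suffix(".raw"))


def read_cube(path: str | Path, format: str | None = None) -> HSCube:
    """Read a cube from an ENVI ``.hdr``(+raw) pair or an ``.npz`` archive.

    The format is inferred from the extension when not given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "envi" if path.suffix.lower() == ".hdr" else "array-archive"
    if format == "envi":
        return _read_envi(path)
    if format == "array-archive":
        with np.load(path, allow_pickle=False) as npz:
            data = npz["data"]
            wav = npz["wavelengths"].tolist() if "wavelengths" in npz else None
            name = str(npz["name"]) if "name" in npz else path.stem
        return HSCube(data, wavelengths=wav, name=name)
    raise ValueError(f"unknown cube format {format!r}")


def write_cube(cube: HSCube, path: str | Path, format: str | None = None) -> Path:
    """Write a cube; returns the path written (the ``.hdr`` for ENVI)."""
    path = Path(path)
    if format is None:
        format = "envi" if path.suffix.lower() == ".hdr" else "array-archive"
    if format == "envi":
        _write_envi(cube, path)
        return path
    if format == "array-archive":
        payload = {"data": cube.data, "name": np.str_(cube.name)}
        if cube.wavelengths is not None:
            payload["wavelengths"] = np.asarray(cube.wavelengths)
        np.savez_compressed(path, **payload)
        return path
    raise ValueError(f"unknown cube format {format!r}")


# --------------------------------------------------------------------------
# Masks and 8-bit images
# --------------------------------------------------------------------------

def read_mask(path: str | Path) -> LabelMask:
    """Read a label mask from a PNG/TIFF image of small integer values."""
    arr = _read_image(path)
    if arr.ndim == 3:
        raise ValueError(f"mask image {path} has {arr.shape[2]} channels; need 1")
    return LabelMask(arr.astype(np.int64))


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    _write_image(mask.labels.astype(np.uint8), path)
    return Path(path)


def _read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    from PIL import Image

    return np.asarray(Image.open(path))


def _write_image(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


# --------------------------------------------------------------------------
# Metric reports
# --------------------------------------------------------------------------

def write_metrics_report(report, path: str | Path) -> Path:
    """Write a metrics report as a two-column CSV (metric, value).

    The config echo (ws, k_ssn, seed, ...) is appended as ``config.<key>``
    rows so a report always states how it was produced.
    """
    rows = list(report.to_rows())
    for key, val in sorted(report.config_echo.items()):
        rows.append((f"config.{key}", val))
    if not all(np.isfinite(v) for _, v in rows if isinstance(v, float)):
        raise ValueError("refusing to write non-finite metric values")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("metric,value\n")
        for name, val in rows:
            fh.write(f"{name},{val!r}\n" if isinstance(val, str) else f"{name},{val}\n")
    logger.info("wrote metrics report to %s", path)
    return path


def read_metrics_report(path: str | Path) -> dict[str, float | str]:
    """Read back a metrics CSV as a flat dict (floats where possible)."""
    out: dict[str, float | str] = {}
    lines = Path(path).read_text().strip().splitlines()
    for line in lines[1:]:
        name, _, val = line.partition(",")
        try:
            out[name] = float(val)
        except ValueError:
            out[name] = val.strip("'\"")
    return out
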