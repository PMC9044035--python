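"""Hypercube container, reflectance calibration, and ENVI/TIFF/NPZ I/O.

A hypercube is a rows x cols x bands reflectance grid with an explicit,
strictly increasing per-band wavelength table (nm).  Reflectance is kept
on the *fraction* scale ([0, 1]) internally; the percent scale is an I/O
presentation.  Calibration converts raw sensor frames to reflectance
with white and dark reference frames:

    R = (raw - dark) / (white - dark)

per pixel and per band, optionally expressed as a percentage.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import tifffile

from .exceptions import EmptySelectionError, FormatError, MetadataError

_SCALE_MAX = {"fraction": 1.0, "percent": 100.0}
# Specular highlights may exceed the white panel; values are capped at
# 1.5x the nominal scale maximum.
_HEADROOM = 1.5


@dataclass
class Hypercube:
    """A rows x cols x bands reflectance image with wavelength metadata.

    Parameters
    ----------
    values : ndarray, shape (rows, cols, bands)
        Reflectance grid.  Finite, non-negative, at most 1.5x the scale
        maximum (specular headroom).
    wavelengths : ndarray, shape (bands,)
        Per-band center wavelengths in nm, strictly increasing.  For
        ``scale="arbitrary"`` (e.g. PCA component stacks) the entries are
        component labels rather than physical wavelengths.
    scale : {"fraction", "percent", "arbitrary"}
        Declared reflectance scale.  "arbitrary" skips range validation.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    scale: str = "fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"expected 3-D values, got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise MetadataError(
                f"wavelength table length {len(self.wavelengths)} != band count "
                f"{self.values.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise MetadataError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("values contain non-finite entries")
        if self.scale in _SCALE_MAX:
            vmax = _SCALE_MAX[self.scale] * _HEADROOM
            if self.values.min() < 0 or self.values.max() > vmax:
                raise FormatError(
                    f"values outside [0, {vmax}] for scale '{self.scale}'"
                )
        elif self.scale != "arbitrary":
            raise MetadataError(f"unknown scale '{self.scale}'")

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def bands(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_fraction(self) -> "Hypercube":
        if self.scale == "fraction":
            return self
        if self.scale == "percent":
            return Hypercube(self.values / 100.0, self.wavelengths, "fraction")
        raise MetadataError("cannot rescale an arbitrary-scale cube")

    def to_percent(self) -> "Hypercube":
        if self.scale == "percent":
            return self
        if self.scale == "fraction":
            return Hypercube(self.values * 100.0, self.wavelengths, "percent")
        raise MetadataError("cannot rescale an arbitrary-scale cube")


@dataclass
class ReferenceFrames:
    """Raw target frame plus dark and white reference frames.

    All three grids share one shape (rows x cols x bands).  ``dark`` is
    recorded with the lens closed (0% reflectance); ``white`` images a
    high-reflectance panel.
    """

    raw: np.ndarray
    dark: np.ndarray
    white: np.ndarray
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        self.white = np.asarray(self.white, dtype=np.float64)
        if not (self.raw.shape == self.dark.shape == self.white.shape):
            raise FormatError("raw/dark/white shapes differ")
        if self.raw.ndim != 3:
            raise FormatError("reference frames must be rows x cols x bands")


class CalibrationResult(NamedTuple):
    cube: Hypercube
    flagged: np.ndarray  # bool, True where white - dark <= eps (dead pixels)


def calibrate(
    frames: ReferenceFrames,
    *,
    scale: str = "fraction",
    denom_eps: float = 1e-6,
    clip_max: float = _HEADROOM,
) -> CalibrationResult:
    """Convert raw counts to reflectance with white/dark references.

    Pixels whose white-minus-dark denominator is <= ``denom_eps`` are
    reported in ``flagged`` (and computed against the clamped
    denominator) rather than raising: dead sensor elements are a data
    quality issue, not a caller error.  Output is clipped to
    ``[0, clip_max]`` on the fraction scale to cap specular highlights.
    """
    denom = frames.white - frames.dark
    flagged = denom <= denom_eps
    refl = (frames.raw - frames.dark) / np.maximum(denom, denom_eps)
    refl = np.clip(refl, 0.0, clip_max)
    wl = frames.wavelengths
    if wl is None:
        wl = np.arange(frames.raw.shape[2], dtype=float)
    if scale == "percent":
        refl = refl * 100.0
    elif scale != "fraction":
        raise MetadataError(f"unsupported output scale '{scale}'")
    return CalibrationResult(Hypercube(refl, wl, scale), flagged)


def spectral_subset(cube: Hypercube, lo: float, hi: float) -> Hypercube:
    """Retain exactly the bands with lo <= wavelength <= hi (nm)."""
    if lo >= hi:
        raise ValueError(f"require lo < hi, got {lo} >= {hi}")
    keep = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
    if not keep.any():
        raise EmptySelectionError(f"no bands in window [{lo}, {hi}] nm")
    return Hypercube(cube.values[:, :, keep], cube.wavelengths[keep], cube.scale)


def band_global_means(cube: Hypercube) -> np.ndarray:
    """Per-band mean reflectance over all pixels (float64 vector)."""
    return cube.values.mean(axis=(0, 1), dtype=np.float64)


# ---------------------------------------------------------------------------
# I/O.  ENVI band-sequential (header + raw) is the canonical on-disk
# format; multi-band TIFF is supported for interchange; NPZ is the fast
# internal cache.
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16, 1: np.uint8}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "tiff"
    if suffix == ".npz":
        return "npz"
    return "envi"


def write_hypercube(cube: Hypercube, path: str | Path, format: str | None = None) -> Path:
    """Write a cube to disk; returns the data path written.

    ENVI output writes ``<path>`` (band-sequential float32) plus
    ``<path>.hdr``; TIFF writes one page per band with the wavelength
    table in the image description; NPZ bundles values + metadata.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        np.savez_compressed(
            path, values=cube.values, wavelengths=cube.wavelengths,
            scale=np.array(cube.scale),
        )
    elif fmt == "tiff":
        meta = json.dumps({"wavelengths": cube.wavelengths.tolist(), "scale": cube.scale})
        tifffile.imwrite(
            path, np.moveaxis(cube.values, 2, 0), description=meta,
            photometric="minisblack",
        )
    elif fmt == "envi":
        data = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype=np.float32)
        data.tofile(path)
        wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
        hdr = (
            "ENVI\n"
            f"samples = {cube.cols}\n"
            f"lines = {cube.rows}\n"
            f"bands = {cube.bands}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
            "interleave = bsq\n"
            "byte order = 0\n"
            f"reflectance scale = {cube.scale}\n"
            "wavelength units = Nanometers\n"
            f"wavelength = {{ {wl} }}\n"
        )
        Path(str(path) + ".hdr").write_text(hdr)
    else:
        raise ValueError(f"unknown format '{fmt}'")
    return path


def _parse_envi_header(text: str) -> dict:
    # key = value, where value may be a { ... } block spanning lines
    fields: dict[str, str] = {}
    for m in re.finditer(
        r"^\s*([a-z][a-z0-9 ]*?)\s*=\s*(\{[^}]*\}|[^\n]*)", text,
        flags=re.MULTILINE | re.IGNORECASE | re.DOTALL,
    ):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def _read_envi(path: Path, on_missing_wavelengths: str) -> Hypercube:
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise MetadataError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
    except KeyError as exc:
        raise MetadataError(f"ENVI header missing field: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise FormatError(f"only BSQ interleave supported, got '{interleave}'")
    data = np.fromfile(path, dtype=dtype)
    if data.size != samples * lines * bands:
        raise FormatError(
            f"data size {data.size} != samples*lines*bands "
            f"{samples * lines * bands}"
        )
    values = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
    wl = _wavelengths_from_header(fields, bands, path, on_missing_wavelengths)
    scale = fields.get("reflectance scale", "fraction")
    return Hypercube(values, wl, scale)


def _wavelengths_from_header(
    fields: dict, bands: int, path: Path, on_missing: str
) -> np.ndarray:
    if "wavelength" in fields:
        wl = np.array(
            [float(x) for x in fields["wavelength"].strip("{} \n").split(",") if x.strip()]
        )
        if len(wl) != bands:
            raise MetadataError(
                f"header lists {len(wl)} wavelengths for {bands} bands"
            )
        return wl
    return _fallback_wavelengths(bands, path, on_missing)


def _fallback_wavelengths(bands: int, path: Path, on_missing: str) -> np.ndarray:
    sidecar = Path(str(path) + ".wavelengths.csv")
    if sidecar.exists():
        wl = np.loadtxt(sidecar, delimiter=",", ndmin=1)
        if len(wl) != bands:
            raise MetadataError(
                f"sidecar lists {len(wl)} wavelengths for {bands} bands"
            )
        return wl
    if on_missing == "uniform":
        warnings.warn(
            f"{path}: no wavelength metadata; using a uniform band-index grid",
            stacklevel=3,
        )
        return np.arange(bands, dtype=float)
    raise MetadataError(f"{path}: no wavelength metadata (header or sidecar)")


def _read_tiff(path: Path, on_missing_wavelengths: str) -> Hypercube:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description or ""
    if arr.ndim == 2:
        arr = arr[None]
    values = np.moveaxis(arr, 0, 2)
    bands = values.shape[2]
    wl = None
    scale = "fraction"
    if desc:
        try:
            meta = json.loads(desc)
            wl = np.asarray(meta["wavelengths"], dtype=float)
            scale = meta.get("scale", "fraction")
        except (json.JSONDecodeError, KeyError, TypeError):
            wl = None
    if wl is not None:
        if len(wl) != bands:
            raise MetadataError(f"TIFF lists {len(wl)} wavelengths for {bands} pages")
    else:
        wl = _fallback_wavelengths(bands, path, on_missing_wavelengths)
    return Hypercube(values, wl, scale)


def read_hypercube(
    path: str | Path,
    format: str | None = None,
    *,
    on_missing_wavelengths: str = "error",
) -> Hypercube:
    """Read a cube from ENVI, TIFF, or NPZ.

    ``on_missing_wavelengths``: "error" (default) raises
    :class:`MetadataError` when neither the header nor a
    ``<path>.wavelengths.csv`` sidecar provides a table; "uniform" falls
    back to a band-index grid with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "npz":
        with np.load(path) as z:
            return Hypercube(z["values"], z["wavelengths"], str(z["scale"]))
    if fmt == "tiff":
        return _read_tiff(path, on_missing_wavelengths)
    if fmt == "envi":
        return _read_envi(path, on_missing_wavelengths)
    raise ValueError(f"unknown format '{fmt}'")
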