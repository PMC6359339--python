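"""Hypercube container, ENVI I/O, reflectance calibration and spectral cropping.

A hypercube is a 3D reflectance (or raw-count) array with two spatial axes
(scan lines x samples) and one spectral axis of band-center wavelengths in
nanometres.  Raw detector counts are converted to reflectance with white
(~99 % reflective) and dark-current reference frames:

    R = (I_raw - I_dark) / (I_white - I_dark)

ENVI files are stored as an ASCII ``.hdr`` plus a flat binary raster; BIL
(line-interleaved) and BSQ (band-sequential) interleaves are supported, with
float32 storage.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthAxis",
    "CubeKind",
    "Hypercube",
    "CalibrationFrames",
    "FormatError",
    "read_envi",
    "write_envi",
    "calibrate_reflectance",
    "crop_spectral",
    "band_image",
    "nearest_band",
]

#: entries of (white - dark) smaller than this magnitude are floored to it,
#: so dead detector pixels yield large-but-finite reflectance, not inf
DENOM_FLOOR = 1e-9


class FormatError(ValueError):
    """Malformed or unsupported ENVI file."""


class CubeKind(str, Enum):
    RAW = "raw"
    REFLECTANCE = "reflectance"
    PREPROCESSED = "preprocessed"


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing band-center wavelengths in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength axis must be a non-empty 1D array")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def index_of(self, nm: float, atol: float = 1e-6) -> int:
        """Index of the band at exactly ``nm`` (within ``atol``)."""
        i = nearest_band(self, nm)
        if abs(self.values[i] - nm) > atol:
            raise KeyError(f"no band at {nm} nm (nearest is {self.values[i]} nm)")
        return i


@dataclass
class Hypercube:
    """3D image stack: ``data[line, sample, band]`` with a wavelength axis."""

    data: np.ndarray
    axis: WavelengthAxis
    kind: CubeKind = CubeKind.RAW

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be 3D (lines, samples, bands)")
        if self.data.shape[2] != len(self.axis):
            raise ValueError(
                f"band dimension {self.data.shape[2]} does not match "
                f"axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("hypercube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class CalibrationFrames:
    """White-reference and dark-current frames.

    Accepted as (samples x bands) single-line references, broadcast over the
    scan-line axis (line-scan instruments record reference lines), or as full
    (lines x samples x bands) frames.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        for name, arr in (("white", self.white), ("dark", self.dark)):
            if arr.ndim not in (2, 3):
                raise ValueError(f"{name} frame must be 2D or 3D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} frame contains non-finite values")


# ---------------------------------------------------------------------------
# ENVI I/O


def _format_header(cube: Hypercube, interleave: str) -> str:
    wl = ", ".join(repr(float(v)) for v in cube.axis.values)
    lines, samples, bands = cube.shape
    return (
        "ENVI\n"
        "description = {seedspec hypercube}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )


def write_envi(cube: Hypercube, header_path: str | Path, interleave: str = "bil") -> Path:
    """Write ``cube`` as an ENVI header + float32 binary raster.

    The raster is written next to the header with a ``.dat`` suffix.
    Returns the header path.
    """
    interleave = interleave.lower()
    if interleave not in ("bil", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r} (use bil or bsq)")
    header_path = Path(header_path)
    raster_path = header_path.with_suffix(".dat")
    if interleave == "bil":
        # (lines, bands, samples)
        arr = np.transpose(cube.data, (0, 2, 1))
    else:
        # (bands, lines, samples)
        arr = np.transpose(cube.data, (2, 0, 1))
    header_path.write_text(_format_header(cube, interleave))
    arr.astype("<f4").tofile(raster_path)
    return header_path


_LIST_RE = re.compile(r"\{(.*)\}", re.S)


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic line)")
    fields: dict[str, str] = {}
    # join continuation lines of { ... } blocks
    body = text.split("\n", 1)[1] if "\n" in text else ""
    entries = re.findall(r"^([\w ]+?)\s*=\s*((?:\{[^}]*\})|[^\n]*)", body, re.M)
    for key, val in entries:
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read an ENVI cube; the wavelength list in the header becomes the axis."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_header(header_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        interleave = fields["interleave"].lower()
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required key: {exc}") from exc

    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength metadata")
    m = _LIST_RE.search(fields["wavelength"])
    if m is None:
        raise FormatError("malformed wavelength list in ENVI header")
    wavelengths = np.array([float(t) for t in m.group(1).split(",") if t.strip()])
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    if interleave not in ("bil", "bsq"):
        raise FormatError(f"unsupported interleave {interleave!r} (only bil/bsq)")
    dtypes = {4: "<f4", 5: "<f8", 1: "u1", 2: "<i2", 12: "<u2"}
    if dtype_code not in dtypes:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(dtypes[dtype_code])

    raster_path = None
    for cand in (header_path.with_suffix(".dat"), header_path.with_suffix(".img"),
                 header_path.with_suffix(".raw"), header_path.with_suffix("")):
        if cand != header_path and cand.exists():
            raster_path = cand
            break
    if raster_path is None:
        raise FileNotFoundError(f"no raster file found next to {header_path}")

    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(raster_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"raster has {raw.size} values, header implies {expected} "
            f"({lines}x{samples}x{bands})"
        )
    if interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    return Hypercube(np.ascontiguousarray(data, dtype=float),
                     WavelengthAxis(wavelengths), CubeKind.RAW)


# ---------------------------------------------------------------------------
# Calibration and spectral selection


def calibrate_reflectance(raw: Hypercube, frames: CalibrationFrames) -> Hypercube:
    """Convert raw counts to reflectance: ``R = (I - I_dark)/(I_white - I_dark)``.

    Denominator entries with magnitude below :data:`DENOM_FLOOR` (dead
    detector pixels) are floored, and the number of floored entries is
    reported via a warning.  Reflectance is *not* clipped to [0, 1]; noise
    may push values slightly outside.
    """
    white, dark = frames.white, frames.dark
    denom = white - dark
    bad = np.abs(denom) < DENOM_FLOOR
    n_bad = int(np.count_nonzero(bad))
    if n_bad:
        denom = np.where(bad, DENOM_FLOOR, denom)
        warnings.warn(
            f"calibrate_reflectance: floored {n_bad} near-zero (white - dark) "
            f"entries to {DENOM_FLOOR}", RuntimeWarning, stacklevel=2)
    refl = (raw.data - dark) / denom
    return Hypercube(refl, raw.axis, CubeKind.REFLECTANCE)


def crop_spectral(cube: Hypercube, lo_nm: float, hi_nm: float) -> Hypercube:
    """Keep bands with ``lo_nm <= wavelength <= hi_nm`` (inclusive)."""
    if not lo_nm < hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    wl = cube.axis.values
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if not keep.any():
        raise ValueError(
            f"spectral crop {lo_nm}-{hi_nm} nm retains no bands "
            f"(axis spans {wl[0]}-{wl[-1]} nm)")
    return Hypercube(cube.data[:, :, keep], WavelengthAxis(wl[keep]), cube.kind)


def nearest_band(axis: WavelengthAxis, target_nm: float) -> int:
    """Index of the band nearest ``target_nm``; ties go to the lower wavelength."""
    d = np.abs(axis.values - target_nm)
    return int(np.argmin(d))  # argmin returns the first (lower-nm) minimum


def band_image(cube: Hypercube, target_nm: float) -> tuple[np.ndarray, float]:
    """2D slice at the band nearest ``target_nm``.

    Returns ``(image, actual_nm)`` so callers know which band was used.
    """
    i = nearest_band(cube.axis, target_nm)
    return cube.data[:, :, i], float(cube.axis.values[i])
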