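"""Spectral pretreatments applied per pixel spectrum, plus scan-line baseline
correction.

Six pretreatments are supported, matching the usual chemometrics menu for
NIR reflectance work: raw (identity), SNV, max/mean/range normalization and
Savitzky-Golay smoothing.  SNV centers each spectrum and scales it to unit
sample standard deviation, which removes per-pixel multiplicative scatter;
the normalizations rescale by a per-spectrum statistic; smoothing suppresses
detector noise while leaving low-order spectral shape intact.

Baseline correction targets the line-to-line intensity shifts of push-broom
(line-scan) acquisition: for every scan line and band the median over that
line's *background* pixels is subtracted, so a constant offset added to an
entire line cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .hypercube import CubeKind, Hypercube

__all__ = [
    "PretreatmentSpec",
    "DegenerateSpectrumError",
    "baseline_correct",
    "snv",
    "normalize",
    "smooth",
    "apply_pretreatment",
    "PRETREATMENT_METHODS",
]

PRETREATMENT_METHODS = ("raw", "snv", "max", "mean", "range", "smoothing")


class DegenerateSpectrumError(ValueError):
    """A spectrum whose pretreatment denominator is zero (e.g. constant)."""


@dataclass(frozen=True)
class PretreatmentSpec:
    """Which pretreatment to run and, for smoothing, its filter parameters."""

    method: str = "raw"
    smoothing_window: int = 11
    smoothing_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.method not in PRETREATMENT_METHODS:
            raise ValueError(
                f"unknown pretreatment {self.method!r}; "
                f"choose from {PRETREATMENT_METHODS}")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 3")
        if not 0 <= self.smoothing_polyorder < self.smoothing_window:
            raise ValueError("smoothing_polyorder must be in [0, window)")


def baseline_correct(
    cube: Hypercube,
    background: np.ndarray,
) -> Hypercube:
    """Flatten line-to-line drift using each scan line's background pixels.

    For every scan line and band the median over that line's background
    pixels is taken as the line's offset, and the deviation of that offset
    from the scene-wide background median (per band) is subtracted.  After
    correction all lines share the same background median, while the
    absolute reflectance scale is preserved.  ``background`` is a 2D boolean
    array (True = background) of the cube's spatial shape.  Lines with no
    background pixels get offset 0 and a warning.
    """
    background = np.asarray(background, dtype=bool)
    if background.shape != cube.shape[:2]:
        raise ValueError("background mask shape does not match cube spatial shape")
    out = cube.data.copy()
    line_med = np.full((cube.n_lines, cube.n_bands), np.nan)
    empty_lines = 0
    for i in range(cube.n_lines):
        bg = background[i]
        if not bg.any():
            empty_lines += 1
            continue
        line_med[i] = np.median(cube.data[i, bg, :], axis=0)
    if np.all(np.isnan(line_med)):
        warnings.warn("baseline_correct: no background pixels anywhere; "
                      "cube returned unchanged", RuntimeWarning, stacklevel=2)
        return Hypercube(out, cube.axis, cube.kind)
    scene_med = np.nanmedian(line_med, axis=0)
    for i in range(cube.n_lines):
        if not np.isnan(line_med[i, 0]):
            out[i] -= line_med[i] - scene_med
    if empty_lines:
        warnings.warn(
            f"baseline_correct: {empty_lines} scan line(s) had no background "
            "pixels; offset 0 used", RuntimeWarning, stacklevel=2)
    return Hypercube(out, cube.axis, cube.kind)


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean) / sample SD (ddof=1)."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv requires a 1D spectrum of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSpectrumError("constant spectrum has zero variance")
    return (x - x.mean()) / sd


def normalize(spectrum: np.ndarray, method: str) -> np.ndarray:
    """Max, mean or range normalization of one spectrum."""
    x = np.asarray(spectrum, dtype=float)
    if method == "max":
        d = x.max()
        if d == 0:
            raise DegenerateSpectrumError("max normalization: max(x) == 0")
        return x / d
    if method == "mean":
        d = x.mean()
        if d == 0:
            raise DegenerateSpectrumError("mean normalization: mean(x) == 0")
        return x / d
    if method == "range":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateSpectrumError("range normalization: max(x) == min(x)")
        return (x - lo) / (hi - lo)
    raise ValueError(f"unknown normalization method {method!r}")


def smooth(spectrum: np.ndarray, spec: PretreatmentSpec) -> np.ndarray:
    """Savitzky-Golay smoothing; edges fitted by the window polynomial."""
    x = np.asarray(spectrum, dtype=float)
    if spec.smoothing_window > x.size:
        raise ValueError(
            f"smoothing window {spec.smoothing_window} exceeds spectrum "
            f"length {x.size}")
    return savgol_filter(x, spec.smoothing_window, spec.smoothing_polyorder,
                         mode="interp")


def _apply_one(x: np.ndarray, spec: PretreatmentSpec) -> np.ndarray:
    if spec.method == "raw":
        return x
    if spec.method == "snv":
        return snv(x)
    if spec.method in ("max", "mean", "range"):
        return normalize(x, spec.method)
    return smooth(x, spec)


def apply_pretreatment(
    cube: Hypercube,
    spec: PretreatmentSpec,
    foreground: np.ndarray | None = None,
) -> Hypercube:
    """Apply one pretreatment to every foreground pixel spectrum of a cube.

    Background pixels (where ``foreground`` is False) are copied through
    unchanged; pretreatments describe seed spectra, not the plate.  With
    ``foreground=None`` every pixel is treated.  Degenerate spectra (zero
    denominator) are left unchanged and counted in a single summary warning
    rather than aborting the run.
    """
    if foreground is None:
        foreground = np.ones(cube.shape[:2], dtype=bool)
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.shape != cube.shape[:2]:
        raise ValueError("foreground mask shape does not match cube spatial shape")

    out = cube.data.copy()
    if spec.method != "raw":
        rows = out[foreground]  # (n_pixels, n_bands)
        n_degenerate = 0
        if spec.method == "smoothing":
            rows = savgol_filter(rows, spec.smoothing_window,
                                 spec.smoothing_polyorder, axis=1, mode="interp")
        else:
            if spec.method == "snv":
                denom = rows.std(axis=1, ddof=1)
                num = rows - rows.mean(axis=1, keepdims=True)
            elif spec.method == "max":
                denom = rows.max(axis=1)
                num = rows
            elif spec.method == "mean":
                denom = rows.mean(axis=1)
                num = rows
            else:  # range
                lo = rows.min(axis=1, keepdims=True)
                denom = rows.max(axis=1) - lo[:, 0]
                num = rows - lo
            ok = denom != 0
            n_degenerate = int(np.count_nonzero(~ok))
            rows = np.where(ok[:, None], num / np.where(ok, denom, 1.0)[:, None],
                            rows)
        out[foreground] = rows
        if n_degenerate:
            warnings.warn(
                f"apply_pretreatment({spec.method}): {n_degenerate} degenerate "
                "pixel spectra left unchanged", RuntimeWarning, stacklevel=2)
    return Hypercube(out, cube.axis, CubeKind.PREPROCESSED)
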