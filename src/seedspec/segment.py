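"""Seed segmentation: band thresholding, connected-component labeling,
plate-layout class assignment, ROI spectrum extraction and seed-level
train/validation splitting.

Seeds sit on a plate in a regular grid with whole rows sharing a viability
class, so ground truth attaches to detected kernels by binning each kernel's
centroid to a grid row.  All downstream statistics are per-seed, so the
calibration/validation split is stratified *by seed*, never by pixel: all
pixels of one kernel land on the same side of the split, which prevents
leakage between sets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.measure import label as cc_label

from .hypercube import Hypercube, WavelengthAxis

__all__ = [
    "SeedLabelMap",
    "SpectraTable",
    "EmptySceneError",
    "threshold_mask",
    "label_seeds",
    "assign_classes_by_rows",
    "extract_spectra",
    "split_by_seed",
]

VIABLE, NONVIABLE = 1, 0


class EmptySceneError(ValueError):
    """No seed kernels survived segmentation."""


@dataclass
class SeedLabelMap:
    """Per-pixel seed IDs (0 = background) and per-seed classes.

    ``classes`` maps seed ID -> 1 (viable), 0 (nonviable) or None (unknown).
    """

    labels: np.ndarray
    classes: dict[int, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 2D integer array")
        ids = self.seed_ids
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("seed IDs must be contiguous 1..K")
        for sid in ids:
            self.classes.setdefault(int(sid), None)

    @property
    def seed_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_seeds(self) -> int:
        return int(self.seed_ids.size)

    def pixel_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    def save(self, png_path: str | Path) -> Path:
        """16-bit label PNG plus a sibling JSON class map."""
        png_path = Path(png_path)
        Image.fromarray(self.labels.astype(np.uint16)).save(png_path)
        classes = {str(k): v for k, v in self.classes.items()}
        png_path.with_suffix(".json").write_text(json.dumps(classes, indent=1))
        return png_path

    @classmethod
    def load(cls, png_path: str | Path) -> "SeedLabelMap":
        png_path = Path(png_path)
        labels = np.asarray(Image.open(png_path)).astype(np.int64)
        classes_raw = json.loads(png_path.with_suffix(".json").read_text())
        classes = {int(k): v for k, v in classes_raw.items()}
        return cls(labels, classes)


@dataclass
class SpectraTable:
    """Flat per-pixel spectra with class and seed bookkeeping.

    Rows are foreground pixels in raster-scan order; ``y`` is constant within
    a seed.
    """

    X: np.ndarray
    y: np.ndarray
    seed_id: np.ndarray
    axis: WavelengthAxis

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.seed_id = np.asarray(self.seed_id)
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.seed_id.shape != (n,):
            raise ValueError("X, y and seed_id must have aligned rows")
        if self.X.shape[1] != len(self.axis):
            raise ValueError("X column count must match wavelength axis")
        for sid in np.unique(self.seed_id):
            cls = np.unique(self.y[self.seed_id == sid])
            if cls.size > 1:
                raise ValueError(f"seed {sid} carries more than one class")

    @property
    def n_pixels(self) -> int:
        return int(self.X.shape[0])

    @property
    def seeds(self) -> np.ndarray:
        return np.unique(self.seed_id)

    def seed_classes(self) -> dict[int, int]:
        return {int(s): int(self.y[self.seed_id == s][0]) for s in self.seeds}

    def subset_seeds(self, seed_ids: np.ndarray) -> "SpectraTable":
        m = np.isin(self.seed_id, seed_ids)
        return SpectraTable(self.X[m], self.y[m], self.seed_id[m], self.axis)

    def subset_bands(self, nm: np.ndarray | list[float]) -> "SpectraTable":
        idx = [self.axis.index_of(v) for v in np.atleast_1d(nm)]
        return SpectraTable(self.X[:, idx], self.y, self.seed_id,
                            WavelengthAxis(self.axis.values[idx]))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = {"seed_id": self.seed_id, "class": self.y}
        for j, nm in enumerate(self.axis.values):
            cols[f"{nm:g}"] = self.X[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraTable":
        df = pd.read_csv(path)
        wl = [c for c in df.columns if c not in ("seed_id", "class")]
        return cls(df[wl].to_numpy(float), df["class"].to_numpy(),
                   df["seed_id"].to_numpy(), WavelengthAxis([float(c) for c in wl]))


# ---------------------------------------------------------------------------


def threshold_mask(band: np.ndarray, threshold: float,
                   seeds_brighter: bool = True) -> np.ndarray:
    """Binary seed mask from one band image.

    ``seeds_brighter=True`` marks pixels above the threshold as seed; set it
    False for scenes where seeds are darker than the plate.
    """
    band = np.asarray(band, dtype=float)
    if not np.all(np.isfinite(band)):
        raise ValueError("band image contains non-finite values")
    return band > threshold if seeds_brighter else band < threshold


def label_seeds(mask: np.ndarray, min_seed_pixels: int = 20) -> SeedLabelMap:
    """8-connected components of the mask, small components removed.

    IDs are assigned 1..K in raster-scan order of each component's first
    pixel, so labeling is deterministic for a given mask.
    """
    mask = np.asarray(mask, dtype=bool)
    raw = cc_label(mask, connectivity=2)
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    keep = ids[counts >= min_seed_pixels]
    if keep.size == 0:
        raise EmptySceneError(
            f"no components with >= {min_seed_pixels} pixels found")
    # relabel in raster order of first occurrence
    flat = raw.ravel()
    first = {int(i): np.argmax(flat == i) for i in keep}
    order = sorted(first, key=first.get)
    lut = np.zeros(raw.max() + 1, dtype=np.int64)
    for new, old in enumerate(order, start=1):
        lut[old] = new
    return SeedLabelMap(lut[raw])


def assign_classes_by_rows(
    lmap: SeedLabelMap,
    layout: list[int],
    guard_margin: float = 0.1,
) -> SeedLabelMap:
    """Attach a class to every seed from a per-grid-row layout.

    Seed centroids are binned into ``len(layout)`` equal vertical intervals
    spanning the detected centroid range; each seed inherits its row's class.
    A centroid within ``guard_margin`` row-heights of a bin edge is flagged
    unknown (None).  Raises if the binning is inconsistent with the layout
    (an empty row, or one bin mixing two detected rows).
    """
    n_rows = len(layout)
    if n_rows < 1:
        raise ValueError("layout must list at least one row class")
    ids = lmap.seed_ids
    if ids.size == 0:
        raise EmptySceneError("label map has no seeds")
    cy = np.array(ndimage.center_of_mass(lmap.labels > 0, lmap.labels, ids))[:, 0]

    if n_rows == 1:
        classes = {int(s): int(layout[0]) for s in ids}
        return SeedLabelMap(lmap.labels.copy(), classes)

    lo, hi = cy.min(), cy.max()
    pitch = (hi - lo) / (n_rows - 1)
    if pitch <= 0:
        raise ValueError("layout-mismatch: all centroids on one line but "
                         f"{n_rows} rows declared")
    edges = lo - pitch / 2 + pitch * np.arange(n_rows + 1)
    bins = np.clip(np.digitize(cy, edges) - 1, 0, n_rows - 1)
    # each declared row must be occupied, else layout does not match scene
    occupied = np.unique(bins)
    if occupied.size != n_rows:
        raise ValueError(
            f"layout-mismatch: {n_rows} rows declared but only "
            f"{occupied.size} centroid rows detected")
    for b in occupied:
        spread = float(np.ptp(cy[bins == b]))
        if spread > 0.5 * pitch:
            raise ValueError(
                "layout-mismatch: centroid spread within a declared row "
                f"({spread:.1f} px) exceeds half the row pitch; the scene "
                f"does not contain {n_rows} rows")

    classes: dict[int, int | None] = {}
    flagged = 0
    for sid, y, b in zip(ids, cy, bins):
        edge_dist = min(abs(y - edges[b]), abs(y - edges[b + 1]))
        if edge_dist < guard_margin * pitch:
            classes[int(sid)] = None
            flagged += 1
        else:
            classes[int(sid)] = int(layout[b])
    if flagged:
        warnings.warn(
            f"assign_classes_by_rows: {flagged} seed(s) ambiguous between "
            "rows, flagged unknown", RuntimeWarning, stacklevel=2)
    return SeedLabelMap(lmap.labels.copy(), classes)


def extract_spectra(cube: Hypercube, lmap: SeedLabelMap) -> SpectraTable:
    """One table row per foreground pixel of a known-class seed.

    Seeds whose class is unknown are excluded (with a count in a warning).
    Row order is raster scan of the label image.
    """
    if lmap.labels.shape != cube.shape[:2]:
        raise ValueError("label map and cube spatial shapes differ")
    known = [s for s, c in lmap.classes.items() if c is not None]
    skipped = lmap.n_seeds - len(known)
    if skipped:
        warnings.warn(
            f"extract_spectra: excluded {skipped} seed(s) with unknown class",
            RuntimeWarning, stacklevel=2)
    m = np.isin(lmap.labels, known)
    if not m.any():
        raise EmptySceneError("no pixels from seeds with known class")
    sid = lmap.labels[m]
    y = np.array([lmap.classes[int(s)] for s in sid])
    return SpectraTable(cube.data[m], y, sid, cube.axis)


def split_by_seed(
    table: SpectraTable,
    calib_fraction: float = 0.75,
    seed: int = 0,
) -> tuple[SpectraTable, SpectraTable]:
    """Seed-level, class-stratified calibration/validation split.

    Within each class the seeds are shuffled (reproducibly, by ``seed``) and
    ``round(calib_fraction * n)`` go to calibration.  No kernel's pixels
    straddle the split.
    """
    if not 0 < calib_fraction < 1:
        raise ValueError("calib_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seed_cls = table.seed_classes()
    calib_ids: list[int] = []
    valid_ids: list[int] = []
    for cls in sorted(set(seed_cls.values())):
        members = np.array(sorted(s for s, c in seed_cls.items() if c == cls))
        if members.size < 2:
            raise ValueError(
                f"class {cls} has {members.size} seed(s); need >= 2 to stratify")
        rng.shuffle(members)
        n_cal = int(round(calib_fraction * members.size))
        n_cal = min(max(n_cal, 1), members.size - 1)
        calib_ids.extend(members[:n_cal])
        valid_ids.extend(members[n_cal:])
    return (table.subset_seeds(np.array(calib_ids)),
            table.subset_seeds(np.array(valid_ids)))
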