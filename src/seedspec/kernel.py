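"""Kernel-based (whole-seed) viability classification.

Pixel-level PLS-DA scores are noisy; a single misclassified pixel should not
flip a seed.  The chemical image maps each foreground pixel to its PLS-DA
score, thresholds at 0.5 (strictly) to mark "detected" (viable-looking)
pixels, and aggregates per kernel into a detection rate:

    detection_pct = 100 * n_detected / n_total_pixels_in_seed

A seed is called viable when its detection rate is >= the detection-rate
threshold (the pixel rule is strict >, the seed rule inclusive >=).  The
threshold itself is chosen by sweeping the full 0-100 range on calibration
seeds, tracing the ROC of sensitivity vs specificity (viable = positive),
and picking the rate that minimizes false positives + false negatives —
ties resolved toward fewer false positives, then toward the larger rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pathlib import Path
from dataclasses import dataclass, field
from PIL import Image, ImageDraw

from .hypercube import Hypercube
from .plsda import PLSDAModel, predict_pixels
from .segment import SeedLabelMap

__all__ = [
    "ChemicalImage",
    "SeedDecisionSet",
    "ROCResult",
    "chemical_image",
    "detection_rates",
    "classify_seeds",
    "roc_curve",
    "optimal_detection_rate",
    "seed_accuracy",
    "render_result_map",
]


@dataclass
class ChemicalImage:
    """Per-pixel PLS-DA score map; background is NaN (0 is a legal score)."""

    values: np.ndarray
    binary: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.binary.shape:
            raise ValueError("values and binary shapes differ")


@dataclass
class SeedDecisionSet:
    """Per-seed detection statistics and (optionally) decisions.

    ``table`` columns: seed_id, n_total, n_detected, detection_pct,
    true_class (may be NA), predicted_class (NA until classified).
    """

    table: pd.DataFrame
    detection_rate: float | None = None

    @property
    def seed_ids(self) -> np.ndarray:
        return self.table["seed_id"].to_numpy()

    def with_truth(self) -> pd.DataFrame:
        t = self.table.dropna(subset=["true_class"])
        if t.empty:
            raise ValueError("no seeds with ground-truth class")
        return t


@dataclass
class ROCResult:
    """ROC over detection-rate thresholds, viable = positive class."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    auc: float
    optimal_rate: float | None = None


def chemical_image(cube: Hypercube, lmap: SeedLabelMap,
                   model: PLSDAModel) -> ChemicalImage:
    """Score every foreground pixel of the (pretreated) cube with the model.

    The model may use a waveband subset; those bands are looked up on the
    cube's axis.  Background pixels stay NaN and are never thresholded.
    """
    if lmap.labels.shape != cube.shape[:2]:
        raise ValueError("label map and cube spatial shapes differ")
    band_idx = [cube.axis.index_of(nm) for nm in model.wavelengths.values]
    fg = lmap.labels > 0
    values = np.full(lmap.labels.shape, np.nan)
    binary = np.zeros(lmap.labels.shape, dtype=bool)
    if fg.any():
        X = cube.data[fg][:, band_idx]
        scores, classes = predict_pixels(model, X)
        values[fg] = scores
        binary[fg] = classes.astype(bool)  # strict > 0.5
    return ChemicalImage(values, binary)


def detection_rates(chem: ChemicalImage, lmap: SeedLabelMap) -> SeedDecisionSet:
    """Count detected (score > 0.5) pixels per seed; exact percentages."""
    if chem.values.shape != lmap.labels.shape:
        raise ValueError("chemical image and label map shapes differ")
    rows = []
    for sid in lmap.seed_ids:
        m = lmap.labels == sid
        n_total = int(m.sum())
        n_det = int(np.count_nonzero(chem.binary & m))
        rows.append({
            "seed_id": int(sid),
            "n_total": n_total,
            "n_detected": n_det,
            "detection_pct": 100.0 * n_det / n_total,
            "true_class": lmap.classes.get(int(sid)),
            "predicted_class": pd.NA,
        })
    df = pd.DataFrame(rows)
    df["true_class"] = df["true_class"].astype("Int64")
    df["predicted_class"] = df["predicted_class"].astype("Int64")
    return SeedDecisionSet(df)


def classify_seeds(rates: SeedDecisionSet, detection_rate: float) -> SeedDecisionSet:
    """Viable iff detection_pct >= detection_rate (inclusive seed rule)."""
    if not 0 <= detection_rate <= 100:
        raise ValueError("detection_rate must be in [0, 100]")
    df = rates.table.copy()
    df["predicted_class"] = (df["detection_pct"] >= detection_rate).astype("Int64")
    return SeedDecisionSet(df, detection_rate=float(detection_rate))


def _confusion_at(pct: np.ndarray, truth: np.ndarray, thr: float):
    pred = pct >= thr
    pos, neg = truth == 1, truth == 0
    tp = int(np.count_nonzero(pred & pos))
    fn = int(np.count_nonzero(~pred & pos))
    fp = int(np.count_nonzero(pred & neg))
    tn = int(np.count_nonzero(~pred & neg))
    return tp, fp, tn, fn


def roc_curve(rates: SeedDecisionSet) -> ROCResult:
    """Sweep detection-rate thresholds 0..100 plus all observed rates.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) with viable as the
    positive class.  AUC is the trapezoid area over (1 - specificity,
    sensitivity); because every observed rate is a swept threshold, this
    equals the Mann-Whitney statistic exactly (ties counted half).
    """
    t = rates.with_truth()
    truth = t["true_class"].to_numpy(int)
    pct = t["detection_pct"].to_numpy(float)
    if np.unique(truth).size < 2:
        raise ValueError("ROC undefined: only one true class present")

    thresholds = np.unique(np.concatenate([np.arange(101, dtype=float), pct]))
    tp = np.empty(thresholds.size, int)
    fp = np.empty(thresholds.size, int)
    tn = np.empty(thresholds.size, int)
    fn = np.empty(thresholds.size, int)
    for i, thr in enumerate(thresholds):
        tp[i], fp[i], tn[i], fn[i] = _confusion_at(pct, truth, thr)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)

    fpr = 1.0 - spec
    # anchor (0,0): a threshold above every rate predicts no seed viable
    pts = np.vstack([np.append(fpr, 0.0), np.append(sens, 0.0)]).T
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(thresholds, sens, spec, tp, fp, tn, fn, auc)


def optimal_detection_rate(roc: ROCResult) -> float:
    """Threshold minimizing FP + FN; ties -> fewer FP, then larger rate."""
    cost = roc.fp + roc.fn
    best = np.flatnonzero(cost == cost.min())
    fewest_fp = best[roc.fp[best] == roc.fp[best].min()]
    rate = float(roc.thresholds[fewest_fp].max())
    roc.optimal_rate = rate
    return rate


def seed_accuracy(decisions: SeedDecisionSet) -> pd.DataFrame:
    """Viable / nonviable / total seed-level accuracy (percent)."""
    t = decisions.with_truth()
    if t["predicted_class"].isna().any():
        raise ValueError("seeds not classified yet; call classify_seeds first")
    truth = t["true_class"].to_numpy(int)
    pred = t["predicted_class"].to_numpy(int)
    rows = []
    for name, cls in (("viable", 1), ("nonviable", 0)):
        m = truth == cls
        acc = float(np.mean(pred[m] == cls) * 100) if m.any() else np.nan
        rows.append((name, int(m.sum()), acc))
    rows.append(("total", truth.size, float(np.mean(pred == truth) * 100)))
    return pd.DataFrame(rows, columns=["group", "n", "accuracy_pct"])


def render_result_map(
    lmap: SeedLabelMap,
    decisions: SeedDecisionSet,
    out: str | Path,
    annotate: bool = False,
    scale: int = 1,
) -> Path:
    """Color-coded decision map: viable seeds red, nonviable green, black
    background; optional per-seed detection-percentage annotation."""
    t = decisions.table
    if t["predicted_class"].isna().any():
        raise ValueError("seeds not classified yet; call classify_seeds first")
    pred = dict(zip(t["seed_id"], t["predicted_class"]))
    rgb = np.zeros((*lmap.labels.shape, 3), dtype=np.uint8)
    for sid in lmap.seed_ids:
        color = (255, 0, 0) if pred[int(sid)] == 1 else (0, 255, 0)
        rgb[lmap.labels == sid] = color
    img = Image.fromarray(rgb)
    if scale > 1:
        img = img.resize((img.width * scale, img.height * scale), Image.NEAREST)
    if annotate:
        draw = ImageDraw.Draw(img)
        from scipy import ndimage
        ids = lmap.seed_ids
        cent = ndimage.center_of_mass(lmap.labels > 0, lmap.labels, ids)
        pcts = dict(zip(t["seed_id"], t["detection_pct"]))
        for sid, (cy, cx) in zip(ids, cent):
            draw.text((cx * scale, cy * scale), f"{pcts[int(sid)]:.0f}",
                      fill=(255, 255, 255), anchor="mm")
    out = Path(out)
    img.save(out)
    return out
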