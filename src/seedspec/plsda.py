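"""From-scratch PLS-DA (NIPALS PLS1) with cross-validated latent-variable
selection, VIP scores and VIP-peak waveband selection.

The discriminant model is ordinary PLS1 regression of a 0/1 class dummy
(1 = viable, 0 = nonviable) on mean-centered pixel spectra.  NIPALS builds
components one at a time: the weight vector w_a is the (normalized)
covariance direction X'y, scores t_a = X w_a, X-loadings p_a and y-loading
q_a are least-squares projections on t_a, and X is deflated by t_a p_a'
before the next component (PLS1 needs no y-deflation).  The factor model
collapses to a single regression vector

    beta = W (P'W)^{-1} q,      b0 = y_mean - x_mean . beta

so a raw spectrum is scored as x . beta + b0 and classified viable when the
score exceeds 0.5 (strictly).

The number of latent variables A is chosen by grouped cross-validation:
folds are formed over *seeds* (stratified by class) so pixels of one kernel
never appear on both sides, RMSECV(A) is the root-mean-square of out-of-fold
score errors, and the smallest A attaining the minimum wins.

Variable importance in projection (VIP) summarizes how much each wavelength
contributes to the explained class variance:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ),   SS_a = q_a^2 t_a't_a

with p the number of bands and w_a unit-norm, which gives the identity
sum_j VIP_j^2 = p.  Wavebands are selected as the strict local maxima of the
VIP curve that exceed 1, plus either axis endpoint exceeding 1 (endpoints
cannot be interior peaks).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube import WavelengthAxis
from .segment import SpectraTable

__all__ = [
    "PLSDAModel",
    "VIPResult",
    "fit_plsda",
    "select_latent_variables",
    "predict_pixels",
    "pixel_accuracy",
    "vip_scores",
    "select_wavebands",
    "refit_on_bands",
]

CLASS_THRESHOLD = 0.5


@dataclass
class PLSDAModel:
    """Fitted PLS-DA model: factors, collapsed coefficients and metadata."""

    n_lv: int
    W: np.ndarray            # (bands, A) unit-norm weight vectors
    P: np.ndarray            # (bands, A) X-loadings
    T: np.ndarray            # (n_train, A) training scores
    q: np.ndarray            # (A,) y-loadings
    beta: np.ndarray         # (bands,) regression vector on raw spectra
    b0: float                # intercept
    x_mean: np.ndarray
    y_mean: float
    wavelengths: WavelengthAxis
    rmsecv_curve: np.ndarray | None = None
    class_threshold: float = CLASS_THRESHOLD

    def save(self, path: str | Path) -> Path:
        """JSON bundle: beta, intercept, axis, RMSECV curve."""
        path = Path(path)
        payload = {
            "n_lv": self.n_lv,
            "b0": self.b0,
            "beta": self.beta.tolist(),
            "wavelengths_nm": self.wavelengths.values.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "class_threshold": self.class_threshold,
            "rmsecv_curve": (None if self.rmsecv_curve is None
                             else self.rmsecv_curve.tolist()),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass
class VIPResult:
    """Per-wavelength VIP scores and (after selection) the chosen bands."""

    scores: np.ndarray
    wavelengths: WavelengthAxis
    selected_nm: np.ndarray | None = None
    selection_rule: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        sel = set() if self.selected_nm is None else set(np.round(self.selected_nm, 6))
        df = pd.DataFrame({
            "wavelength_nm": self.wavelengths.values,
            "vip": self.scores,
            "selected": [round(v, 6) in sel for v in self.wavelengths.values],
        })
        df.to_csv(Path(path), index=False)
        return Path(path)


# ---------------------------------------------------------------------------
# NIPALS core


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """NIPALS PLS1 on centered data; returns (W, P, T, q, n_effective)."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    a_eff = 0
    for a in range(n_lv):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break  # residual X carries no covariance with y: rank exhausted
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            break
        P[:, a] = X.T @ t / tt
        q[a] = (yc @ t) / tt
        W[:, a] = w
        T[:, a] = t
        X -= np.outer(t, P[:, a])
        a_eff += 1
    return W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff], a_eff


def _beta_from_factors(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def fit_plsda(train: SpectraTable, n_lv: int) -> PLSDAModel:
    """Fit PLS-DA with a fixed number of latent variables."""
    X, y = train.X, train.y.astype(float)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training set contains a single class; need both 0 and 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("training spectra contain non-finite values")
    max_allowed = min(p, n - 1)
    if not 1 <= n_lv <= max_allowed:
        raise ValueError(f"n_lv must be in [1, {max_allowed}], got {n_lv}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, T, q, a_eff = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    if a_eff < n_lv:
        warnings.warn(
            f"NIPALS stopped at {a_eff} component(s); rank exhausted before "
            f"{n_lv}", RuntimeWarning, stacklevel=2)
    beta = _beta_from_factors(W, P, q)
    b0 = y_mean - float(x_mean @ beta)
    return PLSDAModel(a_eff, W, P, T, q, beta, b0, x_mean, y_mean, train.axis)


# ---------------------------------------------------------------------------
# Cross-validated latent-variable choice


def _grouped_folds(table: SpectraTable, n_folds: int, seed: int,
                   by_seed: bool = True) -> np.ndarray:
    """Fold index per row; folds over seeds (class-stratified) or pixels."""
    rng = np.random.default_rng(seed)
    n = table.n_pixels
    fold = np.empty(n, dtype=int)
    if by_seed:
        seed_cls = table.seed_classes()
        assign: dict[int, int] = {}
        for cls in sorted(set(seed_cls.values())):
            members = np.array(sorted(s for s, c in seed_cls.items() if c == cls))
            rng.shuffle(members)
            for i, s in enumerate(members):
                assign[int(s)] = i % n_folds
        for s, f in assign.items():
            fold[table.seed_id == s] = f
    else:
        fold[:] = rng.permutation(n) % n_folds
    return fold


def select_latent_variables(
    train: SpectraTable,
    max_lv: int = 15,
    n_folds: int = 10,
    seed: int = 0,
    by_seed: bool = True,
) -> PLSDAModel:
    """Choose A by minimizing RMSECV over A = 1..max_lv, then refit.

    RMSECV(A) is computed from out-of-fold predictions with folds grouped at
    the seed level (``by_seed=False`` falls back to pixel-level folds).  Ties
    go to the smallest A (parsimony).  The returned model stores the full
    RMSECV curve.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n, p = train.X.shape
    bound = min(p, n - 1)
    if max_lv > bound:
        warnings.warn(f"max_lv clipped from {max_lv} to {bound}",
                      RuntimeWarning, stacklevel=2)
        max_lv = bound

    fold = _grouped_folds(train, n_folds, seed, by_seed)
    y = train.y.astype(float)
    sse = np.zeros(max_lv)
    n_pred = 0
    for f in range(n_folds):
        test = fold == f
        if not test.any() or test.all():
            continue
        Xtr, ytr = train.X[~test], y[~test]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        W, P, T, q, a_eff = _nipals_pls1(Xtr - xm, ytr - ym, max_lv)
        Xte_c = train.X[test] - xm
        n_pred += int(test.sum())
        for a in range(max_lv):
            a_use = min(a + 1, a_eff)
            beta = _beta_from_factors(W[:, :a_use], P[:, :a_use], q[:a_use])
            pred = Xte_c @ beta + ym
            sse[a] += float(np.sum((pred - y[test]) ** 2))
    rmsecv = np.sqrt(sse / n_pred)
    best_a = int(np.argmin(rmsecv)) + 1  # argmin takes the first minimum
    model = fit_plsda(train, best_a)
    model.rmsecv_curve = rmsecv
    return model


# ---------------------------------------------------------------------------
# Prediction and accuracy


def predict_pixels(model: PLSDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Score ``x . beta + b0`` per row and the strict >0.5 class decision."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.beta.size:
        raise ValueError(
            f"spectrum has {X.shape[1]} bands, model expects {model.beta.size}")
    scores = X @ model.beta + model.b0
    classes = (scores > model.class_threshold).astype(int)
    return scores, classes


def pixel_accuracy(classes: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Viable / nonviable / total accuracy (percent), Table-style."""
    classes = np.asarray(classes)
    truth = np.asarray(truth)
    if classes.shape != truth.shape or classes.size == 0:
        raise ValueError("classes and truth must be equal-length and non-empty")
    rows = []
    for name, cls in (("viable", 1), ("nonviable", 0)):
        m = truth == cls
        acc = float(np.mean(classes[m] == cls) * 100) if m.any() else np.nan
        rows.append((name, int(m.sum()), acc))
    rows.append(("total", truth.size, float(np.mean(classes == truth) * 100)))
    return pd.DataFrame(rows, columns=["group", "n", "accuracy_pct"])


# ---------------------------------------------------------------------------
# VIP


def vip_scores(model: PLSDAModel) -> VIPResult:
    """Wold VIP scores from the fitted factors."""
    if model.W.size == 0 or model.T.size == 0:
        raise ValueError("model has no fitted components")
    p = model.W.shape[0]
    ss = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)  # q_a^2 t_a't_a
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains no class variance")
    contrib = (model.W**2) @ ss  # w_a are unit-norm
    return VIPResult(np.sqrt(p * contrib / total), model.wavelengths)


def select_wavebands(
    vip: VIPResult,
    axis: WavelengthAxis | None = None,
    min_separation: int = 2,
    max_bands: int | None = None,
) -> np.ndarray:
    """Local VIP maxima above 1, plus qualifying axis endpoints.

    Interior peaks are strict 3-point local maxima with score > 1; peaks
    closer than ``min_separation`` bands keep only the higher one.  Either
    endpoint with score > 1 is always included, since an endpoint can never
    be an interior peak.  ``max_bands`` caps the selection at the
    highest-scoring peaks (for building few-band multispectral models).
    Returns selected wavelengths (nm, ascending); an empty selection
    triggers a warning, not an error.
    """
    axis = axis or vip.wavelengths
    s = vip.scores
    if s.size != len(axis):
        raise ValueError("VIP scores and axis lengths differ")
    interior = [j for j in range(1, s.size - 1)
                if s[j] > 1 and s[j] > s[j - 1] and s[j] > s[j + 1]]
    # greedy suppression: highest peak wins within min_separation bands
    kept: list[int] = []
    for j in sorted(interior, key=lambda j: -s[j]):
        if all(abs(j - k) >= min_separation for k in kept):
            kept.append(j)
    for j in (0, s.size - 1):
        if s[j] > 1 and j not in kept:
            kept.append(j)
    if max_bands is not None and len(kept) > max_bands:
        kept = sorted(kept, key=lambda j: -s[j])[:max_bands]
    if not kept:
        warnings.warn("select_wavebands: no VIP scores above 1; empty selection",
                      RuntimeWarning, stacklevel=2)
        sel = np.array([])
    else:
        sel = np.sort(axis.values[sorted(kept)])
    vip.selected_nm = sel
    vip.selection_rule = {"threshold": 1.0, "min_separation_bands": min_separation,
                          "max_bands": max_bands}
    return sel


def refit_on_bands(
    train: SpectraTable,
    selected_nm: np.ndarray | list[float],
    max_lv: int = 15,
    n_folds: int = 10,
    seed: int = 0,
) -> PLSDAModel:
    """Refit PLS-DA (with its own RMSECV search) on a waveband subset."""
    selected_nm = np.atleast_1d(np.asarray(selected_nm, dtype=float))
    if selected_nm.size == 0:
        raise ValueError("selected_nm must be non-empty")
    sub = train.subset_bands(selected_nm)  # KeyError if a band is off-axis
    return select_latent_variables(sub, max_lv=max_lv, n_folds=n_folds, seed=seed)
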