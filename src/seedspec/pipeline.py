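"""End-to-end pipeline: calibrate -> baseline -> segment -> pretreat ->
PLS-DA -> VIP refit -> chemical image -> detection-rate ROC -> seed calls.

`RunConfig` holds every knob; `run_pipeline` executes the whole chain on
either real ENVI files or a synthetic scene spec and returns (and optionally
writes) a results bundle.  The optimal detection rate is always learned on
calibration seeds only and applied unchanged to validation seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hypercube as hc
from . import kernel as kn
from . import plsda as pls
from . import preprocess as pp
from . import segment as seg
from . import synth

__all__ = ["RunConfig", "run_pipeline", "simulate_scene"]

log = logging.getLogger("seedspec")

BUNDLE_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: ENVI paths (``cube_hdr`` + ``white_hdr`` +
    ``dark_hdr``) or a synthetic ``scene``.
    """

    # input: real files ...
    cube_hdr: str | None = None
    white_hdr: str | None = None
    dark_hdr: str | None = None
    layout: list[int] | None = None
    # ... or synthetic scene
    scene: synth.SceneSpec | None = None

    # spectral window (nm)
    crop_lo_nm: float = 1000.0
    crop_hi_nm: float = 1800.0
    # mask
    mask_band_nm: float = 1300.0
    mask_threshold: float = 0.7
    seeds_brighter: bool = False
    min_seed_pixels: int = 20
    # pretreatment
    pretreatment: pp.PretreatmentSpec = field(
        default_factory=lambda: pp.PretreatmentSpec("snv"))
    # split / CV
    calib_fraction: float = 0.75
    split_seed: int = 0
    cv_folds: int = 10
    max_lv: int = 15
    # VIP
    vip_enable: bool = True
    vip_min_separation: int = 2
    vip_max_bands: int | None = 7  # band budget of a practical multispectral camera
    # detection
    use_optimal_rate: bool = True
    fixed_rate: float = 50.0
    # outputs
    out_dir: str | None = None

    def __post_init__(self) -> None:
        real = self.cube_hdr is not None
        if real == (self.scene is not None):
            raise ValueError("exactly one input source: ENVI paths XOR scene spec")
        if real and (self.white_hdr is None or self.dark_hdr is None):
            raise ValueError("real input requires white and dark reference files")


def simulate_scene(spec_path: str | Path, out_dir: str | Path) -> dict[str, Path]:
    """Render the scene in a SceneSpec JSON and write ENVI + truth files."""
    spec = synth.SceneSpec.from_json(spec_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw, frames, truth = synth.render_scene(spec)
    paths = {
        "cube": hc.write_envi(raw, out_dir / "scene.hdr"),
        "white": hc.write_envi(
            hc.Hypercube(frames.white[None, :, :], raw.axis), out_dir / "white.hdr"),
        "dark": hc.write_envi(
            hc.Hypercube(frames.dark[None, :, :], raw.axis), out_dir / "dark.hdr"),
        "truth": truth.save(out_dir / "truth.png"),
    }
    return paths


def _load_inputs(config: RunConfig):
    if config.scene is not None:
        raw, frames, _truth = synth.render_scene(config.scene)
        layout = list(config.scene.class_layout)
        return raw, frames, layout
    raw = hc.read_envi(config.cube_hdr)
    white = hc.read_envi(config.white_hdr).data
    dark = hc.read_envi(config.dark_hdr).data
    if white.shape[0] == 1:
        white = white[0]
    if dark.shape[0] == 1:
        dark = dark[0]
    if config.layout is None:
        raise ValueError("real input requires a row-class layout")
    return raw, hc.CalibrationFrames(white, dark), list(config.layout)


def _accuracy_dict(df) -> dict:
    return {row.group: row.accuracy_pct for row in df.itertuples()}


def _evaluate_model(model, name, cube_pre, lmap, calib_ids, valid_ids,
                    calib, valid, config, out_dir):
    """Chemical image, ROC on calibration seeds, optimal rate, decisions."""
    chem = kn.chemical_image(cube_pre, lmap, model)
    rates = kn.detection_rates(chem, lmap)

    calib_rates = kn.SeedDecisionSet(
        rates.table[rates.table.seed_id.isin(calib_ids)].reset_index(drop=True))
    valid_rates = kn.SeedDecisionSet(
        rates.table[rates.table.seed_id.isin(valid_ids)].reset_index(drop=True))

    roc = kn.roc_curve(calib_rates)
    opt = kn.optimal_detection_rate(roc)
    rate = opt if config.use_optimal_rate else config.fixed_rate
    log.info("%s model: AUC=%.4f optimal detection rate=%.1f%% (using %.1f%%)",
             name, roc.auc, opt, rate)

    res = {"auc_calibration": roc.auc, "optimal_detection_rate_pct": opt,
           "detection_rate_used_pct": rate, "n_lv": model.n_lv,
           "wavelengths_nm": model.wavelengths.values.tolist()}
    for split_name, split_rates, table in (("calibration", calib_rates, calib),
                                           ("validation", valid_rates, valid)):
        dec = kn.classify_seeds(split_rates, rate)
        dec50 = kn.classify_seeds(split_rates, 50.0)
        res[f"seed_accuracy_{split_name}"] = _accuracy_dict(kn.seed_accuracy(dec))
        res[f"seed_accuracy_{split_name}_rate50"] = _accuracy_dict(
            kn.seed_accuracy(dec50))
        scores, cls = pls.predict_pixels(
            model, table.subset_bands(model.wavelengths.values).X)
        res[f"pixel_accuracy_{split_name}"] = _accuracy_dict(
            pls.pixel_accuracy(cls, table.y))
    # plate-wide seed accuracy (calibration + validation at the learned rate)
    res["seed_accuracy_all"] = _accuracy_dict(
        kn.seed_accuracy(kn.classify_seeds(rates, rate)))
    if out_dir is not None:
        kn.render_result_map(lmap, kn.classify_seeds(rates, rate),
                             out_dir / f"map_{name}_rate{rate:.0f}.png")
        kn.render_result_map(lmap, kn.classify_seeds(rates, 50.0),
                             out_dir / f"map_{name}_rate50.png")
    return res


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the results bundle as a dict."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    raw, frames, layout = _load_inputs(config)
    log.info("loaded raw cube %s, %d-row layout", raw.shape, len(layout))

    refl = hc.calibrate_reflectance(raw, frames)
    refl = hc.crop_spectral(refl, config.crop_lo_nm, config.crop_hi_nm)
    log.info("calibrated and cropped to %.0f-%.0f nm: %d bands",
             config.crop_lo_nm, config.crop_hi_nm, refl.n_bands)

    band, actual_nm = hc.band_image(refl, config.mask_band_nm)
    mask = seg.threshold_mask(band, config.mask_threshold, config.seeds_brighter)
    refl = pp.baseline_correct(refl, ~mask)
    # re-threshold after flattening line drift, then label kernels
    band, _ = hc.band_image(refl, config.mask_band_nm)
    mask = seg.threshold_mask(band, config.mask_threshold, config.seeds_brighter)
    lmap = seg.label_seeds(mask, config.min_seed_pixels)
    lmap = seg.assign_classes_by_rows(lmap, layout)
    log.info("mask at %.0f nm (threshold %.2f): %d seeds",
             actual_nm, config.mask_threshold, lmap.n_seeds)

    cube_pre = pp.apply_pretreatment(refl, config.pretreatment, mask)
    table = seg.extract_spectra(cube_pre, lmap)
    calib, valid = seg.split_by_seed(table, config.calib_fraction,
                                     config.split_seed)
    calib_ids, valid_ids = set(map(int, calib.seeds)), set(map(int, valid.seeds))
    log.info("pretreatment=%s; %d calibration / %d validation seeds "
             "(%d / %d pixels)", config.pretreatment.method, len(calib_ids),
             len(valid_ids), calib.n_pixels, valid.n_pixels)

    full_model = pls.select_latent_variables(
        calib, max_lv=config.max_lv, n_folds=config.cv_folds,
        seed=config.split_seed)
    log.info("full-band model: %d latent variables (RMSECV %.4f)",
             full_model.n_lv, float(full_model.rmsecv_curve[full_model.n_lv - 1]))

    results: dict = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "config": {
            "pretreatment": config.pretreatment.method,
            "crop_nm": [config.crop_lo_nm, config.crop_hi_nm],
            "mask": {"band_nm": actual_nm, "threshold": config.mask_threshold,
                     "seeds_brighter": config.seeds_brighter},
            "calib_fraction": config.calib_fraction,
            "cv_folds": config.cv_folds, "max_lv": config.max_lv,
            "split_seed": config.split_seed,
            "use_optimal_rate": config.use_optimal_rate,
        },
        "n_seeds": lmap.n_seeds,
        "rmsecv_curve": full_model.rmsecv_curve.tolist(),
        "full": _evaluate_model(full_model, "full", cube_pre, lmap, calib_ids,
                                valid_ids, calib, valid, config, out_dir),
    }

    if config.vip_enable:
        vip = pls.vip_scores(full_model)
        selected = pls.select_wavebands(
            vip, min_separation=config.vip_min_separation)
        log.info("VIP selected %d wavebands: %s", selected.size,
                 np.round(selected, 1).tolist())
        results["vip_selected_nm"] = selected.tolist()
        model_bands = selected
        if config.vip_max_bands is not None and selected.size > config.vip_max_bands:
            model_bands = pls.select_wavebands(
                pls.vip_scores(full_model),
                min_separation=config.vip_min_separation,
                max_bands=config.vip_max_bands)
            log.info("VIP model capped to %d bands: %s", model_bands.size,
                     np.round(model_bands, 1).tolist())
        results["vip_model_bands_nm"] = model_bands.tolist()
        if selected.size:
            vip_model = pls.refit_on_bands(
                calib, model_bands, max_lv=config.max_lv,
                n_folds=config.cv_folds, seed=config.split_seed)
            results["vip"] = _evaluate_model(
                vip_model, "vip", cube_pre, lmap, calib_ids, valid_ids,
                calib, valid, config, out_dir)
            if out_dir is not None:
                vip.to_csv(out_dir / "vip_curve.csv")
                vip_model.save(out_dir / "model_vip.json")

    if out_dir is not None:
        full_model.save(out_dir / "model_full.json")
        table.to_csv(out_dir / "spectra.csv")
        (out_dir / "results.json").write_text(json.dumps(results, indent=1))
        log.info("results bundle written to %s", out_dir)
    return results
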