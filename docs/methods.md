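# Methods

## Model and pipeline

The discrimination model is PLS1 regression of a class dummy
(0 = nonviable, 1 = viable) on mean-centered pixel reflectance spectra,
fitted by NIPALS with X-deflation only (with a single response, y-deflation
has no effect on predictions). After A components the factor model is
collapsed to a regression vector `β = W(PᵀW)⁻¹q` and intercept
`β₀ = ȳ − x̄·β`, so a raw spectrum is scored as `x·β + β₀`. Pixel
classification is strict: viable iff score > 0.5 (a score of exactly 0.5 is
nonviable). The seed-level rule is inclusive: a seed is viable iff its
detection rate (percentage of pixels scored viable) is ≥ the detection-rate
threshold. These two boundary conventions are deliberately asymmetric and
are relied on by the tests.

The per-seed detection rate is swept over every integer 0–100 plus every
observed rate; sensitivity and specificity (viable = positive) at each
threshold give the ROC, and the AUC is the trapezoid area over
(1 − specificity, sensitivity) with a (0, 0) anchor for the
nothing-is-viable end. Because all observed rates are in the sweep, the
trapezoid AUC equals the Mann–Whitney pair-counting statistic exactly (ties
half-weighted); the test suite asserts this to 1e−12. The optimal detection
rate minimizes FP + FN on *calibration* seeds only — ties resolved toward
fewer false positives, then toward the larger threshold (stricter on
false positives, matching the economics of discarding seed lots) — and is
applied unchanged to validation seeds.

Latent-variable count A minimizes RMSECV over A = 1..max_lv. Folds are
formed over seeds, stratified by class, so no kernel's pixels appear on
both sides of any fold; ties in the curve go to the smallest A. Each fold
is fitted once at max_lv and prediction errors for all smaller A are read
off the incremental factor expansion. Pixel-level folds are available
behind a flag (`by_seed=False`) but are not the default, since pixel
leakage between folds inflates apparent accuracy.

VIP scores use the Wold definition
`VIP_j = sqrt(p · Σ_a SS_a (w_ja)² / Σ_a SS_a)` with `SS_a = q_a² t_aᵀt_a`
and unit-norm weight vectors, which yields the identity `Σ_j VIP_j² = p`.
Waveband selection keeps strict 3-point local maxima of the VIP curve with
score > 1 (axis endpoints qualify whenever their score exceeds 1, since an
endpoint can never be an interior maximum), suppresses peaks closer than a
configurable number of bands (default 2, higher peak wins), and can cap the
selection at the top-k peaks by score. The pipeline's few-band model uses
k = 7, the band budget a practical multispectral camera might carry.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| spectral window | 1000–1800 nm | region retained before modelling; above 1800 nm the synthetic detector adds no class information |
| mask band / threshold | 1300 nm / 0.70 reflectance | seed/background split; seeds darker than the bright plate by default (polarity configurable) |
| min_seed_pixels | 20 | components smaller than this are treated as debris |
| calibration fraction | 0.75 | seed-level, class-stratified split |
| CV folds | 10 | seed-grouped; configurable upward for large pixel sets |
| max latent variables | 15 | RMSECV search bound (clipped to rank with a warning) |
| pretreatment | SNV | per-pixel; raw/max/mean/range/Savitzky–Golay also available |
| smoothing | window 11, order 2 | conventional spectroscopy default |
| class threshold | 0.5 | pixel score cut, strict > |
| VIP cap | 7 bands | few-band refit budget |

## Baseline correction

Line-scan acquisition leaves additive line-to-line intensity shifts. The
correction estimates, per scan line and band, the median over that line's
background pixels and subtracts its deviation from the scene-wide
background median. All lines end with equal background medians while the
absolute reflectance scale is preserved (so the segmentation threshold
remains meaningful); a line with no background pixels is left unshifted
with a warning. The operator is intentionally simple — it targets exactly
the per-line additive drift the generator produces; polynomial or
asymmetric-least-squares baselines are out of scope.

## Synthetic scenes

The generator emulates what the pipeline consumes, not soybean radiometry:

* a bright plate (reflectance 0.90) with darker seed disks (~0.45) in a
  regular grid, so one band near 1300 nm segments the scene;
* a smooth seed spectrum with peaks near 1300/1600 nm and troughs near
  1200/1400 nm on a gentle slope;
* a subtle class difference: nonviable seeds get Gaussian absorption dips
  (default depth 0.016, width ~20 nm) at 1165, 1335 and 1405 nm — bands in
  the protein/fatty-acid overtone region; the subtractive (absorption)
  direction reflects the compositional changes of seed aging, though the
  method is sign-agnostic;
* three distortions, chosen because they are precisely what the
  preprocessing stages target: per-pixel lognormal multiplicative scatter
  (SD 0.05; removed by SNV), per-line additive drift (SD 0.01; removed by
  baseline correction), and i.i.d. Gaussian detector noise (SD 0.024).

Raw counts are synthesized as `R·(white − dark) + dark` from single-line
white/dark references (~3000 / 100 counts with a mild spectral envelope),
so reflectance calibration inverts the construction exactly when all noise
terms are zero — a closure property the tests assert.

Two presets exist. `default_plate_scene()` is the study condition: a
10×10 plate, alternating viable/nonviable rows, 256 bands over
1000–2500 nm, with `noise_sd = 0.024` calibrated once so that full-band
pixel-level validation accuracy lands in the 80–90 % range — hard enough
that pixel classification is visibly imperfect, while kernel aggregation
still recovers nearly every seed. `separable_scene()` (dip depth 0.09,
noise 0.006) makes both the full-band and the 7-band model essentially
perfect at the pixel level; it isolates the band-selection machinery from
noise effects when comparing few-band against full-band models.

What the generator does *not* model: touching or elliptical seeds,
radiometrically faithful soybean spectra, optical point-spread, wavelength
miscalibration, spatially correlated noise. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under controlled distortions, not instrument-level performance on real
seed lots.

## Reported quantities

Seed-level accuracies from replicated runs are reported over **all plate
seeds** (calibration + validation), classified at the detection rate
learned on calibration seeds only. With the largest-threshold tie rule the
optimal rate sits exactly at the smallest calibration viable detection
rate, so a validation seed slightly below it is occasionally missed; the
plate-wide figure reflects how such a sorter would actually be judged (all
seeds pass through it) and is the package's standard aggregate. Both
per-split and plate-wide numbers appear in every results bundle.

Problem sizes used by the replicated studies: 20 default plates and 5
separable plates of 100 seeds each (~5 200 foreground pixels, 137 bands
after cropping), 10-fold seed-grouped CV, search over 15 latent variables.
These sizes give stable replicate statistics while a full study (tests plus
acceptance script) completes in well under a minute.

## Numerical choices and degenerate inputs

* `(white − dark)` entries with magnitude < 1e−9 are floored to 1e−9 (dead
  detector pixels produce large finite reflectance, never inf) and counted
  in a warning.
* SNV uses the sample (n−1) standard deviation; constant spectra raise a
  degenerate-spectrum error pixel-by-pixel, and cube-level pretreatment
  collects them into one warning instead of aborting.
* NIPALS stops early when the residual covariance `Xᵀy` or a score norm
  falls below 1e−12 (rank exhaustion); the model keeps the components
  actually fitted and warns.
* Nearest-band lookup breaks equidistant ties toward the lower wavelength.
* Seed IDs are assigned in raster-scan order of each component's first
  pixel, making labelling deterministic.
* ENVI rasters are stored little-endian float32; the wavelength axis is
  written at full precision in the ASCII header. BIL and BSQ interleaves
  are supported (BIP is not).
* All stochastic steps (scene rendering, splits, CV folds) flow from
  explicit integer seeds; identical configuration + seeds reproduce
  bit-identical bundles.

## Known limitations

* PLS1 only — two classes; multi-class PLS2 discrimination is out of scope.
* The baseline operator assumes background pixels exist on most scan lines.
* Row-layout class assignment requires an approximately regular grid; it
  flags (rather than guesses) seeds whose centroid falls within 10 % of a
  row-bin edge.
* VIP peak selection inherits the usual caveat that contiguous correlated
  bands can trade places between adjacent grid points from run to run; the
  recovery tests therefore accept a selected band within two grid spacings
  of an injected one.
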