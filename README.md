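# mirdx

Quantitative mid-infrared spectroscopy of cerebral-microdialysate
metabolites: an end-to-end, fully synthetic re-implementation of a
quantum-cascade-laser (QCL) monitoring pipeline for **glucose, lactate and
pyruvate** in the brain extracellular fluid of traumatic-brain-injury
patients.

Bedside microdialysis today yields hourly vials analysed by an enzymatic
colorimetric analyser. Mid-IR transmission spectroscopy of the dialysate in
the 982–1258 cm⁻¹ fingerprint window offers reagent-free, near-continuous
monitoring instead: each analyte has distinct C–O/C–C vibrational bands
(glucose 1036, 1080, 1108, 1152 cm⁻¹; lactate 1042, 1086, 1124 cm⁻¹;
pyruvate 1176 cm⁻¹), and absorbance is additive and proportional to
concentration × path-length (Beer–Lambert). `mirdx` implements the whole
quantification workflow and, because no public spectra exist for this
instrument class at these conditions, ships a physics-based spectrum
emulator so every stage is testable from a clean checkout.

## What the package does

* **`mirdx.synthspec`** — the instrument emulator: pseudo-Voigt band
  libraries, Beer–Lambert mixtures at a 76 μm path-length on a 2 cm⁻¹
  grid, sweep-averaged white noise, baseline offset and drift, response
  jitter, bubble artifacts, pooled (3–4 h) patient-like time-series, and
  rejection-sampled concentration designs. The design sampler draws each
  analyte from the **maximum-entropy density on [min, max] with prescribed
  mean and SD** — `f(u) ∝ exp(αu + βu²)`, the exponential family whose
  log-concave branch is the truncated normal — by rejection from a uniform
  proposal, so the design reproduces all four stated distribution
  properties (e.g. glucose mean 2.34 mM, SD 1.52 mM on [0.02, 5] mM).
* **`mirdx.preprocess`** — sweep averaging, single-point baseline
  correction (anchors 1180 cm⁻¹, or 1080 cm⁻¹ for pyruvate), truncation
  to 1025–1150 cm⁻¹, first differencing, MAD-based outlier screening and
  peak-height extraction.
* **`mirdx.chemometrics`** — NIPALS PLS2 regression (mean-centered, fixed
  deflation order, deterministic sign convention), k-fold RMSECV and
  marginal-decrement component selection, 19/13/14 train/validation/test
  splitting, RMSE evaluation.
* **`mirdx.calibstats`** — standard curves (OLS with n−2 residual SD),
  detection limits **LOD = 3σ/S, LOQ = 10σ/S**, and concentration
  distinguishability by one-way ANOVA + Tukey HSD over a replicated
  dilution ladder.
* **`mirdx.pipeline` / `mirdx.cli`** — orchestration, plain-CSV/JSON I/O,
  validated YAML configuration and the `mirdx` command
  (`simulate`, `calibrate`, `predict`, `monitor`, `report`).

## Worked example

```python
from mirdx import synthspec
from mirdx.config import PipelineConfig
from mirdx.pipeline import run_calibration_workflow, run_monitoring_workflow

report, model = run_calibration_workflow(PipelineConfig(seed=2))
print(report.summary())

profile = synthspec.random_walk_profile(
    synthspec.PATIENT_RANGES["patient1"], hours=48, seed=2
)
series = synthspec.generate_patient_series(profile, hours=48, pooled_from=3, seed=2)
print(run_monitoring_workflow(model, series).summary())
```

prints

```
Calibration run
  spectra measured: 50  flagged as outliers: 4  retained: 46
  selected PLSR components: 3
  test-set RMSE (mM): glucose 0.608, lactate 0.691, pyruvate 0.065
  standard curves (peak cm^-1, R^2, LOD mM, LOQ mM, ANOVA mM):
    glucose     1036 0.9972 0.350 1.167 0.50
    lactate     1124 0.9955 0.567 1.890 0.80
    pyruvate    1176 0.8907 0.157 0.523 0.25

Monitoring run
  pooled points: 16
  glucose   RMSE 0.262 mM   predicted-vs-reference slope 1.402 intercept -0.442 R^2 0.746
  lactate   RMSE 0.892 mM   predicted-vs-reference slope 0.775 intercept 1.074 R^2 0.837
  pyruvate  RMSE 0.094 mM   predicted-vs-reference slope -0.005 intercept 0.172 R^2 0.000
```

Reading this: of the 50 emulated campaign spectra, the 4 bubble-artifact
spectra are screened out; 5-fold RMSECV on the 32 tuning spectra flattens
after 3 latent components; the 14-spectrum test set is predicted to a few
tenths of a mM for glucose and lactate, while pyruvate — present at 30–50×
lower concentrations with its only band at 1176 cm⁻¹, outside the retained
window — carries no usable signal (monitoring R² ≈ 0), reproducing the
known sensitivity deficit of this measurement for pyruvate. The standard
curves give 3σ/S detection limits of a few tenths of a mM and a resolvable
concentration step of a few tenths of a mM from the ANOVA/Tukey ladder.

The same workflow is available from the shell:

```bash
mirdx simulate  --config cfg.yaml --out run/
mirdx calibrate --spectra run/spectra --design run/design.csv \
                --config cfg.yaml --out run/model.json
mirdx predict   --model run/model.json --spectra run/spectra
mirdx monitor   --model run/model.json --series run/series
```

where `cfg.yaml` needs only a `seed:` entry (every other setting has the
protocol default and can be overridden).

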