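# Methods

`mirdx` models bedside quantification of glucose, lactate and pyruvate in
cerebral microdialysate from mid-IR transmission spectra. This note
documents the model, the emulator's assumptions, the numerical choices,
and what the synthetic studies do and do not demonstrate.

## Measurement model

A spectrum is absorbance A(ν) (AU) on a uniform wavenumber grid, by default
982–1258 cm⁻¹ at 2 cm⁻¹ (139 points) — the tuning range of an
external-cavity QCL transmission instrument with a 76 μm flow-cell, with
perfusion fluid as background. Absorbance of a dissolved mixture follows
the Beer–Lambert law:

    A(ν) = s · (L / 76 μm) · Σᵢ cᵢ εᵢ(ν)  +  b  +  d·(ν − ν̄)  +  η(ν)

* `cᵢ` — analyte concentrations (mM); `εᵢ(ν)` — absorptivity profiles
  (AU · mM⁻¹ at the 76 μm reference path).
* `η` — i.i.d. Gaussian point noise. A stored spectrum is the average of
  `n_sweeps` sweeps (default 80, the instrument's ~5 min averaging); per-sweep
  noise SD is 0.3 mAU, so the stored noise floor is 0.3/√80 ≈ 0.034 mAU.
* `b` — constant baseline offset per measurement (SD 2 mAU), the reason the
  univariate branch applies single-point baseline correction.
* `d` — linear baseline drift (SD 1·10⁻⁴ AU/cm⁻¹), modelling slow
  power-envelope change of the source between background and sample
  acquisition. After first differencing it leaves one coherent nuisance
  direction per spectrum.
* `s` — multiplicative response factor per measurement. In the long
  calibration campaign it has SD 0.18 (gasket compliance, temperature-
  dependent water-background compensation, flow effects); in a short
  single-analyte dilution series measured back-to-back it is a repeatability
  term with SD 0.05.

The three nuisance magnitudes are an *emulator calibration*: they are fixed
so that the synthetic campaign reproduces the documented behaviour of the
real instrument class — a pyruvate prediction floor of ~0.07 mM (set by the
white-noise floor), glucose/lactate test errors of ~0.5/0.8 mM (set by the
response jitter, which lies inside the signal subspace and is therefore
irreducible by extra latent variables), and an RMSECV elbow at three latent
components (set by the drift term, which adds exactly one informative-to-
remove nuisance direction). They are configuration values, not fitted
parameters, and all invariants of the base model (linearity in
concentration, proportionality in path-length) hold exactly because every
term is linear or multiplicative and deterministic at the single-spectrum
level; randomness enters only in the campaign sampler.

### Band model

Each analyte's `εᵢ(ν)` is a sum of pseudo-Voigt bands (50% Lorentzian /
50% Gaussian, FWHM 25 cm⁻¹) at the assigned band positions — glucose 1036
(strongest), 1080, 1108, 1152 cm⁻¹; lactate 1042, 1086 (weak), 1124
(strongest) cm⁻¹; pyruvate 1176 cm⁻¹ only — scaled so that 1 mM at 76 μm
reads 1.0 / 0.8 / 0.7 mAU at the strongest band of glucose / lactate /
pyruvate. True per-band intensities for this instrument are not public;
these defaults keep the analytes' signal-to-noise ordering (pyruvate
hardest) and every value is overridable in the configuration.

A consequence of the Lorentzian tails worth knowing: the 1152 cm⁻¹ glucose
band leaves ≈ 7% of the 1036 cm⁻¹ peak absorbance at the 1180 cm⁻¹ baseline
anchor. Single-point correction therefore removes constant offsets exactly
but biases glucose peak heights low by that fraction — an inherent
limitation of single-point anchoring, shared (more mildly) by the real
measurement.

### Bubble artifacts

A bubble transiting the flow-cell scatters the beam; the emulator
superimposes a broad Gaussian excursion (60–120 cm⁻¹ FWHM, default 50 mAU,
random sign) plus a narrow 6 cm⁻¹ distortion at 40% amplitude, and flags
the spectrum. By default 4 of the 50 campaign spectra are affected,
matching the protocol in which 4 outliers were excluded and 46 spectra
retained.

## Concentration designs: maximum-entropy rejection sampling

The calibration campaign needs a 50-sample design whose per-analyte
distributions have stated mean/SD/min/max (glucose 2.34/1.52/0.02–5.0 mM,
lactate 4.48/2.07/0.5–8.0 mM, pyruvate 0.17/0.07/0.02–0.30 mM). The target
density is the **maximum-entropy density on the admissible interval under
the first two moment constraints**, `f(u) ∝ exp(αu + βu²)` on the unit-
scaled range. This family contains the truncated normal as its log-concave
branch (β < 0; lactate and pyruvate land there) and mildly U-shaped,
edge-heavy designs (β > 0; glucose, whose stated SD of 1.52 mM exceeds the
1.44 mM maximum any distribution-shaped-like-a-truncated-normal can attain
on [0.02, 5] — the uniform limit (max−min)/√12). (α, β) are found by
minimising the convex dual `log Z(θ) − θ·m` (BFGS on a 200-point
Gauss–Legendre quadrature; gradient = moment residual, converged below
1e-8), so the fit is deterministic and the realised design moments match
the stated ones up to sampling error. Sampling is by rejection from the
uniform proposal with the analytic density bound, so no draw can leave
[min, max]. A degenerate interval (min = max) returns constants; a moment
pair with sd² ≥ mean·(1−mean) on the unit scale is infeasible for *any*
distribution and is rejected.

## Preprocessing

Fixed chain, each step deterministic and total on valid input:

* **univariate branch**: average sweeps → single-point baseline correction
  (nearest grid point to the anchor; 1180 cm⁻¹, or 1080 cm⁻¹ for pyruvate,
  which absorbs at 1176 cm⁻¹) → peak height at the nearest grid point.
  Nearest-point convention throughout — on a 2 cm⁻¹ grid interpolation
  buys nothing and exactness aids testing.
* **multivariate branch**: average → truncate to the closed interval
  [1025, 1150] cm⁻¹ (instrument sensitivity degrades outside) → first
  differences `d[j] = A[j+1] − A[j]` on midpoints (length n−1). Raw
  adjacent differences, not ΔA/Δν: on a uniform grid the scale factor is a
  constant and irrelevant to regression. No baseline anchor here —
  differencing removes offsets exactly.
* **outlier screening** replaces visual inspection with a deterministic
  rule: residual of each spectrum from the ensemble median spectrum,
  per-spectrum linear detrend (ordinary baseline offset/drift variation
  must not mask artifacts), score = median |detrended residual|, flag when
  score > 5 × ensemble MAD (median of all pooled |detrended residuals|).
  With all-identical inputs the MAD is zero and nothing is flagged (strict
  inequality). Measured operating characteristics at the default
  threshold: 100% of default-magnitude bubbles flagged, 0 false positives
  over 50 emulated campaigns.

## PLSR calibration

NIPALS PLS2 with column mean-centering only (differenced absorbances share
one scale; no autoscaling), fixed deflation order, and each weight vector
sign-normalised so its largest-magnitude element is positive — fits are
bit-reproducible. The inner power iteration runs to a weight-change norm
below 1e-10 (cap 5000); a component whose singular pair is nearly
degenerate (deep, noise-dominated components) is resolved exactly with the
dominant singular vector of the deflated cross-covariance, the fixed point
the iteration approximates. At full rank the coefficients coincide with
ordinary least squares; against an independent reference PLS
implementation the coefficients agree to 1e-8 on random problems.

Protocol: the 46 retained spectra are split uniformly at random into
training (19), validation (13) and test (14) sets. Component count is
chosen by 5-fold RMSECV for k = 1…10 on the pooled training + validation
rows (the two tuning sets; the spec of fold count is open — 5 is the
configurable default). RMSECV pools held-out squared errors over folds;
the aggregate curve is the root mean of the per-analyte MSECVs (mM,
unweighted; an open choice — flagged, not asserted as the original
protocol's). The **marginal-decrement rule** selects the smallest k whose
relative improvement to k+1 falls below 2% (configurable), i.e. where the
curve starts to flatten; a strictly flat curve selects 1, a curve still
improving at k_max selects k_max. The final model is fit on the training
rows alone; validation RMSE is recorded as confirmation and the test set
is touched once, for the reported RMSE.

Under the default emulation the elbow lands at three components in ≥ 90%
of seeds: two strong analyte directions (glucose, lactate) plus one
drift-nuisance direction that the model must learn to ignore; pyruvate's
band lies outside the retained window, so its tail adds no usable fourth
direction at the default noise floor.

## Univariate statistics

Standard curves are ordinary least squares on all replicate points of a
dilution ladder (default 3 replicates/level, ladders spanning each
analyte's physiological range), with residual SD on n−2 degrees of freedom
and R² the squared correlation of fitted vs observed. Detection limits are
the 3σ convention, LOD = 3σ/S and LOQ = 10σ/S, computed without internal
rounding, so LOQ/LOD = 10/3 identically; they are scale-equivariant (units
of the response cancel). A non-positive slope is rejected as an
uninformative calibration.

Distinguishability: one-way ANOVA across the ladder's concentration
groups; if the omnibus test is significant at α = 0.05, all pairs are
compared with Tukey's honest significant difference (the standard
multiple-comparison default), and the reported step is the smallest ladder
spacing Δ such that *every* pair of groups at least Δ apart separates at
α. If no spacing qualifies the result is "not resolved"; if every group
has zero within-group variance the F statistic is undefined and the
smallest nonzero spacing is returned with a degeneracy warning. Tukey pair
p-values were cross-checked against a max-q permutation oracle (10⁴
permutations) on a small fixture.

## Patient-like monitoring series

Hourly vial concentrations follow smooth random-walk trajectories
(Gaussian-smoothed, σ = 6 h) affinely mapped into per-patient ranges taken
from bedside-analyser records (patient 1: glucose 0.7–1.7, lactate
2.1–9.4, pyruvate 0.03–0.10 mM over ~48 h; patient 2: glucose 1.0–7.4,
lactate 2.2–4.7, pyruvate 0.01–0.17 mM over ~122 h). Consecutive windows
of 3 (or 4) vials are pooled by arithmetic mean — equal vial volumes at
the fixed 0.3 μL/min perfusion rate — a trailing incomplete window is
dropped (48 h / 3 → 16 points; 122 h / 3 → 40), and one spectrum is
emulated per pooled sample with the campaign nuisance model. Monitoring
reports per-analyte RMSE against the pooled references and the least-
squares line of predicted on reference. An optional collection-artifact
dip is not modelled (off by default in concept; trajectories are plain
random walks).

## Determinism and problem sizes

Every stochastic stage derives a named child seed from the single config
seed via a seed sequence; identical configs give bit-identical designs,
spectra, splits, folds and reports. The default study sizes are those of
the emulated protocol itself (50-sample design, 80-sweep averaging,
46-spectrum modelling set, 19/13/14 split, 5 folds, k ≤ 10); the
acceptance script averages design moments over 200 seeds and component
selection over 20 emulated campaigns, sizes chosen to make Monte-Carlo
error small relative to the quantities' tolerances. A full default
calibration run takes on the order of a second on one CPU.

## Limitations

* The emulator omits water-vapour/CO₂ lines, detector nonlinearity,
  absorbance nonlinearity at high concentration, matrix effects of the
  perfusion-fluid electrolytes, and intra-measurement flow dynamics. Its
  nuisance model (offset + linear drift + in-span response jitter + white
  noise) is a deliberate minimal basis for the error structure, not a
  physical instrument model.
* True band intensities and the original design's full sample list are not
  public; absorptivities and the design's distributional family are
  principled reconstructions. Passing tests therefore demonstrate that the
  *pipeline* reproduces the protocol-level behaviour under the stated
  emulation — not field performance on real microdialysate.
* Pyruvate is, by construction and in agreement with the real measurement,
  not quantifiable at physiological levels with this window and noise
  floor; its reported RMSE reflects the prediction collapsing to the
  design mean.
* Single-point baseline anchoring biases glucose peak heights ~7% low via
  band tails (see above); the multivariate branch is unaffected.
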