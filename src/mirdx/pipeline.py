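"""End-to-end orchestration of the calibration and monitoring workflows.

Calibration: rejection-sampled design -> emulated campaign spectra ->
outlier screen -> truncate + first-difference -> random 19/13/14 split ->
k-fold RMSECV -> marginal-decrement component selection -> final PLS2 fit
on the training set -> test-set RMSE, plus the univariate branch (standard
curves, 3-sigma detection limits, ANOVA/Tukey distinguishability) for each
analyte.  Monitoring: a persisted model applied to a pooled patient-like
time-series, scored against the series' reference concentrations.

Every random draw derives from the single config seed, so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from scipy import stats

from . import calibstats, chemometrics, io, preprocess, synthspec
from .chemometrics import CVResult, PLSRModel, SplitIndices
from .config import PipelineConfig
from .synthspec import ANALYTES, Spectrum, TimeSeries

_SEED_ROLES = ("design", "spectra", "split", "cv", "curves")


def derive_seeds(seed: int) -> dict[str, int]:
    """Named, independent child seeds (< 2^31) for each stochastic stage."""
    state = np.random.SeedSequence(seed).generate_state(len(_SEED_ROLES))
    return {
        role: int(value & 0x7FFFFFFF) for role, value in zip(_SEED_ROLES, state)
    }


def preprocess_matrix(
    spectra: Sequence[Spectrum], lo: float, hi: float
) -> np.ndarray:
    """Multivariate branch: truncate to [lo, hi] then first-difference."""
    rows = [
        preprocess.first_difference(preprocess.truncate_range(s, lo, hi)).differences
        for s in spectra
    ]
    return np.array(rows)


@dataclass
class AnalyteCalibration:
    """One row of the univariate calibration table."""

    analyte: str
    peak_center: float
    slope: float
    r_squared: float
    residual_sd: float
    lod: float
    loq: float
    anova_step: float | None

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class CalibrationRunReport:
    """Full record of one calibration run."""

    selected_components: int
    cv: CVResult
    test_rmse: dict[str, float]
    validation_rmse: dict[str, float]
    calibration_table: list[AnalyteCalibration]
    n_spectra: int
    n_flagged: int
    split: SplitIndices
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "selected_components": self.selected_components,
            "rmsecv": {
                "components": self.cv.components.tolist(),
                "aggregate": self.cv.aggregate.tolist(),
                "per_analyte": self.cv.per_analyte.tolist(),
                "analytes": list(self.cv.analytes),
                "n_folds": self.cv.n_folds,
            },
            "test_rmse_mM": self.test_rmse,
            "validation_rmse_mM": self.validation_rmse,
            "calibration_table": [row.to_dict() for row in self.calibration_table],
            "n_spectra": self.n_spectra,
            "n_flagged": self.n_flagged,
            "split_sizes": [
                int(self.split.training.size),
                int(self.split.validation.size),
                int(self.split.test.size),
            ],
            "provenance": self.provenance,
        }

    def summary(self) -> str:
        lines = [
            "Calibration run",
            f"  spectra measured: {self.n_spectra}  flagged as outliers: "
            f"{self.n_flagged}  retained: {self.n_spectra - self.n_flagged}",
            f"  selected PLSR components: {self.selected_components}",
            "  test-set RMSE (mM): "
            + ", ".join(f"{a} {v:.3f}" for a, v in self.test_rmse.items()),
            "  standard curves (peak cm^-1, R^2, LOD mM, LOQ mM, ANOVA mM):",
        ]
        for row in self.calibration_table:
            step = f"{row.anova_step:.2f}" if row.anova_step is not None else "n.r."
            lines.append(
                f"    {row.analyte:9s} {row.peak_center:6.0f} "
                f"{row.r_squared:.4f} {row.lod:.3f} {row.loq:.3f} {step}"
            )
        return "\n".join(lines)


def _standard_curves(config: PipelineConfig, seed: int) -> list[AnalyteCalibration]:
    """Univariate branch: replicate dilution ladders per pure analyte."""
    rng = np.random.default_rng(seed)
    grid = config.generator.build_grid()
    library = config.generator.build_library()
    components = synthspec.library_as_mapping(library)
    gen = config.generator
    cal = config.calibration
    effective_noise = gen.sweep_noise_sd / np.sqrt(gen.n_sweeps)
    anchors = {
        "glucose": config.preprocess.anchor_glucose_lactate,
        "lactate": config.preprocess.anchor_glucose_lactate,
        "pyruvate": config.preprocess.anchor_pyruvate,
    }
    table: list[AnalyteCalibration] = []
    for analyte in ANALYTES:
        center = components[analyte].strongest_center
        levels = cal.levels(analyte)
        concentrations: list[float] = []
        heights: list[float] = []
        groups: dict[float, list[float]] = {level: [] for level in levels}
        for level in levels:
            for _ in range(cal.replicates):
                sample = synthspec.ConcentrationSample(
                    **{a: (level if a == analyte else 0.0) for a in ANALYTES}
                )
                spectrum = synthspec.synthesize_spectrum(
                    sample,
                    library,
                    grid,
                    path_length_um=gen.path_length_um,
                    noise_sd=effective_noise,
                    baseline_offset=rng.normal(0.0, cal.offset_sd),
                    seed=int(rng.integers(2**31)),
                    response_scale=rng.normal(1.0, cal.response_repeatability_sd),
                    n_sweeps_averaged=gen.n_sweeps,
                )
                height = preprocess.peak_height(spectrum, center, anchors[analyte])
                concentrations.append(level)
                heights.append(height)
                groups[level].append(height)
        curve = calibstats.fit_calibration_curve(
            concentrations, heights, analyte=analyte, peak_center=center
        )
        limits = calibstats.detection_limits(curve)
        anova = calibstats.anova_distinguishable_step(groups, alpha=cal.alpha)
        table.append(
            AnalyteCalibration(
                analyte=analyte,
                peak_center=center,
                slope=curve.slope,
                r_squared=curve.r_squared,
                residual_sd=curve.residual_sd,
                lod=limits.lod,
                loq=limits.loq,
                anova_step=anova.distinguishable_step,
            )
        )
    return table


def calibrate_spectra(
    spectra: Sequence[Spectrum],
    concentrations: np.ndarray,
    config: PipelineConfig,
    *,
    seeds: dict[str, int] | None = None,
) -> tuple[CalibrationRunReport, PLSRModel]:
    """Multivariate calibration on measured spectra with known concentrations.

    Screens outliers, truncates and first-differences the retained spectra,
    splits them 19/13/14 (the test partition absorbs any deviation from the
    nominal retained count), selects the component count by k-fold RMSECV on
    the pooled training + validation rows, fits the final model on the
    training rows and scores it on the untouched test rows.
    """
    seeds = seeds or derive_seeds(config.seed)
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.shape[0] != len(spectra):
        raise ValueError("one concentration row per spectrum required")

    report = preprocess.outlier_screen(
        spectra, config.preprocess.outlier_threshold_mad
    )
    kept = report.retained_indices()
    kept_spectra = [spectra[i] for i in kept]
    y = concentrations[kept]
    x = preprocess_matrix(
        kept_spectra, config.preprocess.truncate_lo, config.preprocess.truncate_hi
    )

    sizes = list(config.chemometrics.split_sizes)
    if sum(sizes) != len(kept):
        # Screening need not flag exactly the nominal count; the test
        # partition absorbs the difference.
        sizes[2] = len(kept) - sizes[0] - sizes[1]
        if sizes[2] < 1:
            raise ValueError(
                f"only {len(kept)} spectra retained; cannot form a "
                f"{config.chemometrics.split_sizes} split"
            )
    split = chemometrics.split_dataset(len(kept), tuple(sizes), seeds["split"])

    tuning = np.concatenate([split.training, split.validation])
    cv = chemometrics.kfold_rmsecv(
        x[tuning],
        y[tuning],
        k_max=config.chemometrics.k_max,
        n_folds=config.chemometrics.n_folds,
        seed=seeds["cv"],
        analytes=ANALYTES,
    )
    n_components = chemometrics.select_n_components(
        cv, config.chemometrics.selection_threshold
    )

    descriptor = {
        "truncate_lo": config.preprocess.truncate_lo,
        "truncate_hi": config.preprocess.truncate_hi,
        "difference_order": 1,
    }
    model = chemometrics.fit_plsr(
        x[split.training],
        y[split.training],
        n_components,
        preprocessing=descriptor,
        analytes=ANALYTES,
    )
    validation_rmse = chemometrics.rmse(
        chemometrics.predict(model, x[split.validation]), y[split.validation]
    )
    test_rmse = chemometrics.rmse(
        chemometrics.predict(model, x[split.test]), y[split.test]
    )
    run_report = CalibrationRunReport(
        selected_components=n_components,
        cv=cv,
        test_rmse=dict(zip(ANALYTES, map(float, test_rmse))),
        validation_rmse=dict(zip(ANALYTES, map(float, validation_rmse))),
        calibration_table=[],
        n_spectra=len(spectra),
        n_flagged=report.n_flagged,
        split=split,
        provenance={
            "seed": config.seed,
            "derived_seeds": seeds,
            "config_hash": config.config_hash(),
        },
    )
    return run_report, model


def run_calibration_workflow(
    config: PipelineConfig,
    output_dir: str | Path | None = None,
) -> tuple[CalibrationRunReport, PLSRModel]:
    """Execute the full calibration protocol for one config.

    Generates the design and campaign spectra, runs ``calibrate_spectra``
    and attaches the univariate standard-curve table.
    """
    seeds = derive_seeds(config.seed)
    gen = config.generator
    grid = gen.build_grid()
    library = gen.build_library()

    design = synthspec.sample_design(
        gen.distribution.build(), gen.n_samples, seeds["design"]
    )
    spectra = synthspec.generate_calibration_set(
        design,
        library,
        grid,
        seed=seeds["spectra"],
        noise_sd=gen.sweep_noise_sd,
        n_sweeps=gen.n_sweeps,
        offset_sd=gen.offset_sd,
        slope_sd=gen.slope_sd,
        response_sd=gen.response_sd,
        n_artifacts=gen.n_artifacts,
        bubble_magnitude=gen.bubble_magnitude,
        path_length_um=gen.path_length_um,
    )

    run_report, model = calibrate_spectra(
        spectra, design.as_matrix(), config, seeds=seeds
    )
    run_report.calibration_table = _standard_curves(config, seeds["curves"])

    out = Path(output_dir) if output_dir else (
        Path(config.output_dir) if config.output_dir else None
    )
    if out is not None:
        outliers = preprocess.outlier_screen(
            spectra, config.preprocess.outlier_threshold_mad
        )
        _persist_calibration(
            out, config, design, spectra, outliers, run_report, model
        )
    return run_report, model


def _persist_calibration(
    out: Path,
    config: PipelineConfig,
    design: synthspec.Design,
    spectra: Sequence[Spectrum],
    outliers: preprocess.OutlierReport,
    report: CalibrationRunReport,
    model: PLSRModel,
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    labels = [s.label for s in spectra]
    io.write_design(design, out / "design.csv", labels=labels)
    io.write_manifest(out / "manifest.csv", labels, design.samples, spectra)
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    for spectrum in spectra:
        io.write_spectrum(spectrum, spectra_dir / f"{spectrum.label}.csv")
    io.write_outlier_report(outliers, out / "outliers.csv")
    io.save_model(model, out / "model.json", provenance=report.provenance)
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    (out / "summary.txt").write_text(report.summary() + "\n")


@dataclass
class MonitoringRunReport:
    """Predictions of a persisted model on a pooled monitoring series."""

    timestamps: np.ndarray
    predictions: np.ndarray          # (n_points, n_analytes)
    reference: np.ndarray
    rmse: dict[str, float]
    regression: dict[str, dict[str, float]]  # slope/intercept/r_squared
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "timestamps_h": self.timestamps.tolist(),
            "predictions_mM": self.predictions.tolist(),
            "reference_mM": self.reference.tolist(),
            "rmse_mM": self.rmse,
            "regression": self.regression,
            "provenance": self.provenance,
        }

    def summary(self) -> str:
        lines = [
            "Monitoring run",
            f"  pooled points: {len(self.timestamps)}",
        ]
        for analyte, value in self.rmse.items():
            reg = self.regression[analyte]
            lines.append(
                f"  {analyte:9s} RMSE {value:.3f} mM   predicted-vs-reference "
                f"slope {reg['slope']:.3f} intercept {reg['intercept']:.3f} "
                f"R^2 {reg['r_squared']:.3f}"
            )
        return "\n".join(lines)


def run_monitoring_workflow(
    model: PLSRModel, series: TimeSeries
) -> MonitoringRunReport:
    """Apply a persisted model to a pooled time-series and score it."""
    descriptor = model.preprocessing
    x = preprocess_matrix(
        series.spectra,
        descriptor.get("truncate_lo", preprocess.TRUNCATE_LO),
        descriptor.get("truncate_hi", preprocess.TRUNCATE_HI),
    )
    if x.shape[1] != model.x_mean.size:
        raise ValueError(
            f"series grid yields {x.shape[1]} channels, model expects "
            f"{model.x_mean.size}; grids are incompatible"
        )
    predictions = chemometrics.predict(model, x)
    reference = series.reference_matrix()
    analytes = model.analytes or ANALYTES
    rmse = chemometrics.rmse(predictions, reference)
    regression: dict[str, dict[str, float]] = {}
    for j, analyte in enumerate(analytes):
        if np.ptp(reference[:, j]) == 0.0:
            regression[analyte] = {
                "slope": float("nan"),
                "intercept": float(np.mean(predictions[:, j])),
                "r_squared": float("nan"),
            }
            continue
        fit = stats.linregress(reference[:, j], predictions[:, j])
        regression[analyte] = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue**2),
        }
    return MonitoringRunReport(
        timestamps=series.timestamps,
        predictions=predictions,
        reference=reference,
        rmse=dict(zip(analytes, map(float, rmse))),
        regression=regression,
        provenance={"n_components": model.n_components},
    )
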