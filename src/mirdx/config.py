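"""Validated pipeline configuration.

Every default mirrors the emulated study protocol: 76 um path-length,
982-1258 cm^-1 grid at 2 cm^-1, 80-sweep averaging, 50-sample design with
4 bubble artifacts, 1025-1150 cm^-1 truncation, 19/13/14 split, 5-fold
RMSECV up to 10 components with a 2% marginal-decrement threshold, and
3-replicate standard curves at alpha = 0.05.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from . import preprocess, synthspec
from .synthspec import ComponentSpectrum, DistributionSpec, PeakModel, WavenumberGrid


class PeakSettings(BaseModel):
    center: float
    fwhm: float = synthspec.DEFAULT_FWHM
    relative_height: float = 1.0
    shape: str = "pseudo_voigt"
    mixing: float = synthspec.DEFAULT_VOIGT_MIXING


class ComponentSettings(BaseModel):
    analyte: str
    unit_absorptivity: float
    peaks: list[PeakSettings]

    def build(self) -> ComponentSpectrum:
        return ComponentSpectrum(
            analyte=self.analyte,
            peaks=tuple(PeakModel(**p.model_dump()) for p in self.peaks),
            unit_absorptivity=self.unit_absorptivity,
        )


def _default_library_settings() -> list[ComponentSettings]:
    return [
        ComponentSettings(
            analyte=c.analyte,
            unit_absorptivity=c.unit_absorptivity,
            peaks=[
                PeakSettings(
                    center=p.center,
                    fwhm=p.fwhm,
                    relative_height=p.relative_height,
                    shape=p.shape,
                    mixing=p.mixing,
                )
                for p in c.peaks
            ],
        )
        for c in synthspec.default_component_library()
    ]


class MomentsSettings(BaseModel):
    mean: float
    sd: float
    minimum: float
    maximum: float


class DistributionSettings(BaseModel):
    glucose: MomentsSettings = MomentsSettings(mean=2.34, sd=1.52, minimum=0.02, maximum=5.0)
    lactate: MomentsSettings = MomentsSettings(mean=4.48, sd=2.07, minimum=0.5, maximum=8.0)
    pyruvate: MomentsSettings = MomentsSettings(mean=0.17, sd=0.07, minimum=0.02, maximum=0.30)

    def build(self) -> DistributionSpec:
        return DistributionSpec(
            **{
                analyte: synthspec.AnalyteMoments(**getattr(self, analyte).model_dump())
                for analyte in synthspec.ANALYTES
            }
        )


class GeneratorSettings(BaseModel):
    n_samples: int = 50
    n_artifacts: int = 4
    grid_start: float = 982.0
    grid_stop: float = 1258.0
    grid_resolution: float = 2.0
    path_length_um: float = synthspec.REFERENCE_PATH_UM
    sweep_noise_sd: float = synthspec.SWEEP_NOISE_SD
    n_sweeps: int = synthspec.DEFAULT_N_SWEEPS
    offset_sd: float = synthspec.CAMPAIGN_OFFSET_SD
    slope_sd: float = synthspec.CAMPAIGN_SLOPE_SD
    response_sd: float = synthspec.CAMPAIGN_RESPONSE_SD
    bubble_magnitude: float = synthspec.DEFAULT_BUBBLE_MAGNITUDE
    distribution: DistributionSettings = Field(default_factory=DistributionSettings)
    library: list[ComponentSettings] = Field(default_factory=_default_library_settings)

    def build_grid(self) -> WavenumberGrid:
        import numpy as np

        values = np.arange(
            self.grid_start, self.grid_stop + 0.5 * self.grid_resolution,
            self.grid_resolution,
        )
        return WavenumberGrid(values, resolution=self.grid_resolution)

    def build_library(self) -> list[ComponentSpectrum]:
        return [c.build() for c in self.library]


class PreprocessSettings(BaseModel):
    truncate_lo: float = preprocess.TRUNCATE_LO
    truncate_hi: float = preprocess.TRUNCATE_HI
    outlier_threshold_mad: float = preprocess.OUTLIER_THRESHOLD_MAD
    anchor_glucose_lactate: float = preprocess.ANCHOR_GLUCOSE_LACTATE
    anchor_pyruvate: float = preprocess.ANCHOR_PYRUVATE


class ChemometricsSettings(BaseModel):
    split_sizes: tuple[int, int, int] = (19, 13, 14)
    n_folds: int = 5
    k_max: int = 10
    selection_threshold: float = 0.02

    @model_validator(mode="after")
    def _positive(self) -> "ChemometricsSettings":
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")
        return self


class CalibrationSettings(BaseModel):
    alpha: float = 0.05
    replicates: int = 3
    #: Per-measurement relative response repeatability of a short
    #: single-analyte dilution series (consecutive acquisitions, one gasket).
    response_repeatability_sd: float = 0.05
    offset_sd: float = 1.0e-3
    glucose_levels: list[float] = Field(
        default_factory=lambda: [0.0, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0]
    )
    lactate_levels: list[float] = Field(
        default_factory=lambda: [0.0, 0.2, 0.5, 1.0, 2.0, 4.0, 8.0]
    )
    pyruvate_levels: list[float] = Field(
        default_factory=lambda: [0.0, 0.05, 0.1, 0.2, 0.3, 0.4]
    )

    def levels(self, analyte: str) -> list[float]:
        return getattr(self, f"{analyte}_levels")


class PipelineConfig(BaseModel):
    """Top-level configuration; ``seed`` is required and drives every RNG."""

    seed: int
    output_dir: str | None = None
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    chemometrics: ChemometricsSettings = Field(default_factory=ChemometricsSettings)
    calibration: CalibrationSettings = Field(default_factory=CalibrationSettings)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; validation errors name the field."""
    payload = yaml.safe_load(Path(path).read_text())
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig.model_validate(payload)
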