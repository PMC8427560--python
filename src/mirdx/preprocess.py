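"""Spectral conditioning: sweep averaging, baseline correction, range
truncation, first differencing, outlier screening and peak-height extraction.

Two branches are used downstream, always in this order:

* univariate:    average_sweeps -> baseline_correct -> peak_height
* multivariate:  average_sweeps -> truncate_range -> first_difference

The multivariate branch applies no baseline anchor because differencing
already removes constant offsets exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .synthspec import Spectrum, WavenumberGrid

#: Default retained window (cm^-1) for multivariate modeling; instrument
#: sensitivity degrades outside it.
TRUNCATE_LO = 1025.0
TRUNCATE_HI = 1150.0

#: Default robust-distance multiplier for outlier screening.
OUTLIER_THRESHOLD_MAD = 5.0

#: Baseline anchor points (cm^-1): no analyte band at 1180 for glucose and
#: lactate; pyruvate (which absorbs at 1176) is anchored at 1080 instead.
ANCHOR_GLUCOSE_LACTATE = 1180.0
ANCHOR_PYRUVATE = 1080.0


@dataclass(frozen=True)
class DifferencedSpectrum:
    """First differences of absorbance on the midpoint wavenumber grid."""

    midpoints: np.ndarray
    differences: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "midpoints", np.asarray(self.midpoints, float))
        object.__setattr__(self, "differences", np.asarray(self.differences, float))
        if self.midpoints.shape != self.differences.shape:
            raise ValueError("midpoints and differences must align")


@dataclass(frozen=True)
class OutlierReport:
    """Per-spectrum robust distances and flags at a fixed threshold."""

    labels: tuple[str, ...]
    scores: np.ndarray
    flagged: np.ndarray
    threshold_mad: float
    ensemble_mad: float

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flagged))

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.flagged)


def average_sweeps(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of sweeps acquired on an identical grid."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.grid.values, first.grid.values):
            raise ValueError("all sweeps must share an identical wavenumber grid")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    total = sum(s.n_sweeps_averaged for s in spectra)
    return replace(first, absorbance=mean, n_sweeps_averaged=total)


def baseline_correct(spectrum: Spectrum, anchor: float) -> Spectrum:
    """Single-point baseline correction: subtract the absorbance at the grid
    point nearest ``anchor`` from the whole spectrum (nearest-point
    convention, no interpolation)."""
    index = spectrum.grid.nearest_index(anchor)
    return replace(
        spectrum, absorbance=spectrum.absorbance - spectrum.absorbance[index]
    )


def truncate_range(
    spectrum: Spectrum, lo: float = TRUNCATE_LO, hi: float = TRUNCATE_HI
) -> Spectrum:
    """Keep grid points in the closed interval [lo, hi]."""
    if lo >= hi:
        raise ValueError("lo must be smaller than hi")
    keep = (spectrum.grid.values >= lo) & (spectrum.grid.values <= hi)
    if not keep.any():
        raise ValueError(f"no grid points inside [{lo}, {hi}]")
    grid = WavenumberGrid(
        spectrum.grid.values[keep], resolution=spectrum.grid.resolution
    )
    return replace(spectrum, grid=grid, absorbance=spectrum.absorbance[keep])


def first_difference(spectrum: Spectrum) -> DifferencedSpectrum:
    """d[j] = A[j+1] - A[j] on the midpoint grid (length n-1).

    Removes any constant baseline offset exactly; on a uniform grid the
    omitted 1/delta-nu scale factor is a constant irrelevant to regression.
    """
    if len(spectrum.grid) < 2:
        raise ValueError("need at least two points to difference")
    nu = spectrum.grid.values
    return DifferencedSpectrum(
        midpoints=0.5 * (nu[:-1] + nu[1:]),
        differences=np.diff(spectrum.absorbance),
    )


def outlier_screen(
    spectra: Sequence[Spectrum],
    threshold_mad: float = OUTLIER_THRESHOLD_MAD,
) -> OutlierReport:
    """Flag gross artifacts by robust distance from the ensemble median.

    Each spectrum's residual from the ensemble median spectrum is linearly
    detrended (per-spectrum offset and slope removed, since ordinary baseline
    variation between acquisitions must not mask artifacts); the score is
    the median absolute detrended residual, and a spectrum is flagged when
    its score exceeds ``threshold_mad`` times the ensemble MAD (the median
    of all pooled absolute detrended residuals).  This codifies the visual
    screening a spectroscopist would do: bubbles produce broad curved
    excursions that dwarf both the noise floor and baseline drift.
    """
    if len(spectra) < 3:
        raise ValueError("need at least three spectra to screen")
    stack = np.array([s.absorbance for s in spectra])
    residual = stack - np.median(stack, axis=0)
    nu = spectra[0].grid.values
    basis = np.vander((nu - nu.mean()) / np.ptp(nu), 2)  # [slope, offset]
    coef, *_ = np.linalg.lstsq(basis, residual.T, rcond=None)
    residual = residual - (basis @ coef).T
    scores = np.median(np.abs(residual), axis=1)
    ensemble_mad = float(np.median(np.abs(residual)))
    flagged = scores > threshold_mad * ensemble_mad
    return OutlierReport(
        labels=tuple(s.label for s in spectra),
        scores=scores,
        flagged=flagged,
        threshold_mad=float(threshold_mad),
        ensemble_mad=ensemble_mad,
    )


def peak_height(spectrum: Spectrum, center: float, anchor: float) -> float:
    """Baseline-corrected absorbance (AU) at the grid point nearest ``center``."""
    corrected = baseline_correct(spectrum, anchor)
    return float(corrected.absorbance[spectrum.grid.nearest_index(center)])
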