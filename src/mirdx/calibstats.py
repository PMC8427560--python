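"""Univariate calibration statistics for single-analyte standard curves.

A standard curve regresses baseline-corrected peak height (AU) on
concentration (mM) over a dilution ladder measured in replicate.  From the
ordinary-least-squares line the detection limits follow the 3-sigma
convention: LOD = 3 sigma / S and LOQ = 10 sigma / S, with sigma the
residual SD of the regression (n - 2 denominator) and S the slope.

Independently, concentration distinguishability is assessed the way a
bedside-analyzer comparison would: one-way ANOVA across the ladder's
concentration groups followed by Tukey honest-significant-difference
all-pairs comparison, reporting the smallest ladder spacing at which every
pair of groups that far apart is significantly different.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS standard curve of one analyte at one peak."""

    analyte: str
    peak_center: float
    slope: float            # S, AU per mM
    intercept: float        # AU
    r_squared: float
    residual_sd: float      # sigma, AU
    n_points: int
    replicates_per_point: int

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass(frozen=True)
class DetectionLimits:
    """LOD = 3 sigma/S and LOQ = 10 sigma/S, in mM (LOQ/LOD = 10/3 exactly)."""

    lod: float
    loq: float


@dataclass(frozen=True)
class AnovaLoqResult:
    """Outcome of the ANOVA + Tukey HSD distinguishability analysis.

    ``distinguishable_step`` is the smallest spacing (mM) of the tested
    concentration ladder such that every pair of groups separated by at
    least that spacing differs significantly at ``alpha``; ``None`` when no
    spacing on the ladder achieves this ("not resolved").
    """

    concentrations: tuple[float, ...]
    pair_p_values: dict[tuple[float, float], float]
    alpha: float
    anova_p_value: float
    distinguishable_step: float | None
    degenerate: bool = False


def fit_calibration_curve(
    concentrations: Sequence[float],
    responses: Sequence[float],
    *,
    analyte: str = "",
    peak_center: float = float("nan"),
) -> CalibrationCurve:
    """Ordinary least-squares standard curve over all replicate points.

    ``concentrations`` and ``responses`` are flat, replicate-expanded and
    aligned.  R-squared is the squared correlation between fitted and
    observed responses; the residual SD uses the regression's n - 2 degrees
    of freedom.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise ValueError("concentrations and responses must be aligned 1-D arrays")
    levels, counts = np.unique(c, return_counts=True)
    if levels.size < 3:
        raise ValueError("need at least three distinct concentration levels")
    fit = stats.linregress(c, r)
    fitted = fit.intercept + fit.slope * c
    dof = c.size - 2
    residual_sd = math.sqrt(float(((r - fitted) ** 2).sum()) / dof)
    return CalibrationCurve(
        analyte=analyte,
        peak_center=peak_center,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_sd=residual_sd,
        n_points=int(levels.size),
        replicates_per_point=int(counts.min()),
    )


def detection_limits(curve: CalibrationCurve) -> DetectionLimits:
    """3-sigma/S detection and 10-sigma/S quantification limits (mM).

    No rounding is applied internally; a non-positive slope means the
    calibration carries no information and is rejected.
    """
    if curve.slope <= 0:
        raise ValueError(
            f"calibration slope must be positive (got {curve.slope!r})"
        )
    lod = 3.0 * curve.residual_sd / curve.slope
    loq = 10.0 * curve.residual_sd / curve.slope
    return DetectionLimits(lod=lod, loq=loq)


def anova_distinguishable_step(
    groups: Mapping[float, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
) -> AnovaLoqResult:
    """One-way ANOVA plus Tukey HSD across a replicated concentration ladder.

    Groups are keyed by concentration (mM).  If the omnibus F-test is
    significant at ``alpha``, all pairs are compared with Tukey's honest
    significant difference; the reported step is the smallest ladder
    spacing at which all pairs that far apart separate.  With zero
    within-group variance everywhere the F statistic is undefined; the
    smallest nonzero spacing is returned with a degeneracy warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two concentration groups")
    concentrations = tuple(sorted(groups))
    samples = [np.asarray(groups[c], dtype=float) for c in concentrations]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least two replicates")

    spacings = sorted(
        {
            round(abs(a - b), 12)
            for i, a in enumerate(concentrations)
            for b in concentrations[i + 1 :]
        }
    )
    if all(np.ptp(s) == 0.0 for s in samples):
        warnings.warn(
            "zero within-group variance in every group; distinguishability "
            "is degenerate",
            RuntimeWarning,
        )
        means = [float(np.mean(s)) for s in samples]
        pairs = {}
        step = None
        if len(set(means)) == len(means):
            step = spacings[0]
        return AnovaLoqResult(
            concentrations=concentrations,
            pair_p_values=pairs,
            alpha=alpha,
            anova_p_value=0.0 if len(set(means)) > 1 else 1.0,
            distinguishable_step=step,
            degenerate=True,
        )

    anova = stats.f_oneway(*samples)
    pair_p: dict[tuple[float, float], float] = {}
    step: float | None = None
    if anova.pvalue <= alpha:
        tukey = stats.tukey_hsd(*samples)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                pair_p[(concentrations[i], concentrations[j])] = float(
                    tukey.pvalue[i, j]
                )
        for candidate in spacings:
            wide_pairs = [
                p
                for (a, b), p in pair_p.items()
                if abs(b - a) >= candidate - 1e-12
            ]
            if wide_pairs and all(p <= alpha for p in wide_pairs):
                step = candidate
                break
    return AnovaLoqResult(
        concentrations=concentrations,
        pair_p_values=pair_p,
        alpha=alpha,
        anova_p_value=float(anova.pvalue),
        distinguishable_step=step,
    )
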