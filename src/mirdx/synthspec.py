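"""Synthetic mid-IR data generator for microdialysate metabolite monitoring.

This module emulates everything a quantum-cascade-laser (QCL) transmission
spectrometer would measure in a glucose/lactate/pyruvate quantification
campaign: pure-component absorptivity libraries built from band models,
rejection-sampled concentration designs, Beer-Lambert mixture spectra with
instrument nuisances (noise, baseline offset and drift, response jitter,
bubble artifacts), and pooled patient-like concentration time-series.

The spectral window is the 982-1258 cm^-1 fingerprint region at 2 cm^-1
resolution, where glucose, lactate and pyruvate show distinct C-O / C-C
vibrational bands while water absorption is moderate.  Absorbance is modeled
as additive over co-dissolved absorbers and proportional to concentration
and optical path-length (Beer-Lambert law), with a 76 um reference
path-length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

ANALYTES = ("glucose", "lactate", "pyruvate")

#: Reference optical path-length (um) at which unit absorptivities are quoted.
REFERENCE_PATH_UM = 76.0

#: Default acquisition: per-sweep white-noise SD (AU) and sweeps per spectrum.
#: A stored spectrum is the average of ``DEFAULT_N_SWEEPS`` sweeps, so its
#: effective noise floor is ``SWEEP_NOISE_SD / sqrt(DEFAULT_N_SWEEPS)``.
SWEEP_NOISE_SD = 3.0e-4
DEFAULT_N_SWEEPS = 80

#: Campaign-level nuisance magnitudes (drawn once per measured spectrum):
#: additive baseline offset SD (AU), linear baseline-drift slope SD
#: (AU per cm^-1) and relative multiplicative response jitter SD.
CAMPAIGN_OFFSET_SD = 2.0e-3
CAMPAIGN_SLOPE_SD = 1.0e-4
CAMPAIGN_RESPONSE_SD = 0.18

#: Default broad-excursion magnitude (AU) of a bubble artifact.
DEFAULT_BUBBLE_MAGNITUDE = 0.05

DEFAULT_FWHM = 25.0
DEFAULT_VOIGT_MIXING = 0.5


# ---------------------------------------------------------------------------
# Wavenumber grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly increasing wavenumber axis (cm^-1)."""

    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two wavenumber points")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if np.any(np.abs(steps - self.resolution) > 1e-9):
            raise ValueError("grid spacing must be uniform and equal to resolution")

    @classmethod
    def default(cls) -> "WavenumberGrid":
        """The instrument's tuning range: 982-1258 cm^-1 at 2 cm^-1 (139 points)."""
        return cls(np.arange(982.0, 1258.0 + 1.0, 2.0), resolution=2.0)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber`` (must lie in span)."""
        lo, hi = self.span
        if not (lo <= wavenumber <= hi):
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 outside grid span [{lo}, {hi}]"
            )
        return int(np.argmin(np.abs(self.values - wavenumber)))


# ---------------------------------------------------------------------------
# Component spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakModel:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), relative height.

    ``shape`` is one of ``gaussian``, ``lorentzian`` or ``pseudo_voigt``;
    a pseudo-Voigt is the ``mixing``-weighted sum of a Lorentzian and a
    Gaussian of equal FWHM.
    """

    center: float
    fwhm: float = DEFAULT_FWHM
    relative_height: float = 1.0
    shape: str = "pseudo_voigt"
    mixing: float = DEFAULT_VOIGT_MIXING

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0 < self.relative_height <= 1:
            raise ValueError("relative_height must lie in (0, 1]")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-height band shape evaluated at ``wavenumbers``."""
        nu = np.asarray(wavenumbers, dtype=float)
        sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        gauss = np.exp(-0.5 * ((nu - self.center) / sigma) ** 2)
        half = self.fwhm / 2.0
        lorentz = half**2 / ((nu - self.center) ** 2 + half**2)
        if self.shape == "gaussian":
            return gauss
        if self.shape == "lorentzian":
            return lorentz
        return self.mixing * lorentz + (1.0 - self.mixing) * gauss


@dataclass(frozen=True)
class ComponentSpectrum:
    """Per-analyte molar absorptivity profile built from band models.

    ``unit_absorptivity`` is the absorbance (AU) of a 1 mM solution at the
    reference 76 um path-length, evaluated at the center of the strongest
    band; the full profile is scaled so that the summed band shapes take
    exactly this value there.
    """

    analyte: str
    peaks: tuple[PeakModel, ...]
    unit_absorptivity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        if not self.peaks:
            raise ValueError("component needs at least one peak")
        if self.unit_absorptivity <= 0:
            raise ValueError("unit_absorptivity must be positive")
        strongest = max(p.relative_height for p in self.peaks)
        if abs(strongest - 1.0) > 1e-12:
            raise ValueError("the strongest peak must have relative_height 1")

    @property
    def strongest_center(self) -> float:
        return max(self.peaks, key=lambda p: p.relative_height).center

    def absorptivity(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Absorptivity (AU per mM at 76 um) at the given wavenumbers."""
        nu = np.asarray(wavenumbers, dtype=float)
        raw = np.zeros_like(nu)
        for peak in self.peaks:
            raw += peak.relative_height * peak.profile(nu)
        at_strongest = sum(
            p.relative_height * p.profile(np.array([self.strongest_center]))[0]
            for p in self.peaks
        )
        return raw * (self.unit_absorptivity / at_strongest)


def default_component_library() -> list[ComponentSpectrum]:
    """Band assignments of the three metabolites in the fingerprint window.

    Glucose: C-O stretches at 1036 and 1080 cm^-1 and C-C stretches at 1108
    and 1152 cm^-1, strongest at 1036.  Lactate: C-O bands at 1042 and 1124
    cm^-1 with a low-intensity band at 1086 cm^-1, strongest at 1124.
    Pyruvate: a single strong C-C band at 1176 cm^-1.

    Unit absorptivities (1 mM at 76 um) default to 1.0, 0.8 and 0.7 mAU at
    the strongest band of glucose, lactate and pyruvate respectively, which
    keeps the signal-to-noise ordering of the emulated instrument (pyruvate
    hardest to quantify at physiological levels).
    """
    return [
        ComponentSpectrum(
            "glucose",
            peaks=(
                PeakModel(1036.0, relative_height=1.0),
                PeakModel(1080.0, relative_height=0.9),
                PeakModel(1108.0, relative_height=0.6),
                PeakModel(1152.0, relative_height=0.5),
            ),
            unit_absorptivity=1.0e-3,
        ),
        ComponentSpectrum(
            "lactate",
            peaks=(
                PeakModel(1042.0, relative_height=0.75),
                PeakModel(1086.0, relative_height=0.30),
                PeakModel(1124.0, relative_height=1.0),
            ),
            unit_absorptivity=0.8e-3,
        ),
        ComponentSpectrum(
            "pyruvate",
            peaks=(PeakModel(1176.0, relative_height=1.0),),
            unit_absorptivity=0.7e-3,
        ),
    ]


def library_as_mapping(
    library: Sequence[ComponentSpectrum],
) -> dict[str, ComponentSpectrum]:
    return {component.analyte: component for component in library}


# ---------------------------------------------------------------------------
# Concentration designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyteMoments:
    """Target mean/SD (mM) and admissible range of one analyte's design."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.minimum > self.maximum:
            raise ValueError("minimum must not exceed maximum")
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("mean must lie within [minimum, maximum]")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class DistributionSpec:
    """Per-analyte distribution properties of a concentration design."""

    glucose: AnalyteMoments
    lactate: AnalyteMoments
    pyruvate: AnalyteMoments

    def moments(self, analyte: str) -> AnalyteMoments:
        return getattr(self, analyte)

    @classmethod
    def default(cls) -> "DistributionSpec":
        """The published 50-sample design's distribution properties.

        Mean / SD / max / min in mM: glucose 2.34 / 1.52 / 5.0 / 0.02,
        lactate 4.48 / 2.07 / 8.0 / 0.5, pyruvate 0.17 / 0.07 / 0.30 / 0.02.
        """
        return cls(
            glucose=AnalyteMoments(2.34, 1.52, 0.02, 5.0),
            lactate=AnalyteMoments(4.48, 2.07, 0.5, 8.0),
            pyruvate=AnalyteMoments(0.17, 0.07, 0.02, 0.30),
        )


@dataclass(frozen=True)
class ConcentrationSample:
    """One (glucose, lactate, pyruvate) concentration triplet in mM."""

    glucose: float
    lactate: float
    pyruvate: float

    def __post_init__(self) -> None:
        for name in ANALYTES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} concentration must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.glucose, self.lactate, self.pyruvate], dtype=float)


@dataclass(frozen=True)
class Design:
    """An ordered list of concentration samples plus its generating spec."""

    samples: tuple[ConcentrationSample, ...]
    spec: DistributionSpec
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))

    def __len__(self) -> int:
        return len(self.samples)

    def as_matrix(self) -> np.ndarray:
        """(n_samples, 3) concentration matrix in the fixed analyte order."""
        return np.array([s.as_array() for s in self.samples])


class _MaxEntTarget:
    """Maximum-entropy density on [0, 1] with prescribed mean and variance.

    The density is f(u) proportional to exp(alpha*u + beta*u^2) — the natural
    exponential family whose sufficient statistics are the first two moments.
    Its log-concave branch (beta < 0) is the truncated normal; beta > 0 gives
    the mildly U-shaped, edge-heavy designs whose SD exceeds the uniform limit
    (range/sqrt(12)).  Parameters are found by minimizing the convex dual
    log Z(theta) - theta . m, so the fit is deterministic and exact to solver
    tolerance whenever the moment pair is feasible (sd^2 < mean*(1-mean)).
    """

    _QUAD_POINTS = 200

    def __init__(self, mean: float, sd: float) -> None:
        if not 0.0 < mean < 1.0:
            raise ValueError("scaled mean must lie strictly inside (0, 1)")
        if sd**2 >= mean * (1.0 - mean):
            raise ValueError(
                "requested SD is infeasible for a distribution on the "
                f"stated range (sd^2 = {sd**2:.4g} >= {mean * (1 - mean):.4g})"
            )
        self.mean = mean
        self.sd = sd
        nodes, weights = np.polynomial.legendre.leggauss(self._QUAD_POINTS)
        self._u = 0.5 * (nodes + 1.0)
        self._w = 0.5 * weights
        self.alpha, self.beta = self._solve(mean, sd**2 + mean**2)

    def _dual(self, theta: np.ndarray, m1: float, m2: float):
        expo = theta[0] * self._u + theta[1] * self._u**2
        shift = expo.max()
        q = self._w * np.exp(expo - shift)
        z = q.sum()
        value = np.log(z) + shift - theta[0] * m1 - theta[1] * m2
        grad = np.array(
            [(q * self._u).sum() / z - m1, (q * self._u**2).sum() / z - m2]
        )
        return value, grad

    def _solve(self, m1: float, m2: float) -> tuple[float, float]:
        result = minimize(
            self._dual,
            x0=np.zeros(2),
            args=(m1, m2),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 1000},
        )
        if np.max(np.abs(result.jac)) > 1e-8:
            raise RuntimeError(
                "moment matching did not converge: "
                f"residual {result.jac}, moments ({m1}, {m2})"
            )
        return float(result.x[0]), float(result.x[1])

    def unnormalized_density(self, u: np.ndarray) -> np.ndarray:
        return np.exp(self.alpha * u + self.beta * u**2)

    @property
    def density_bound(self) -> float:
        """Supremum of the unnormalized density on [0, 1] (for rejection)."""
        candidates = [0.0, 1.0]
        if self.beta != 0.0:
            stationary = -self.alpha / (2.0 * self.beta)
            if 0.0 < stationary < 1.0:
                candidates.append(stationary)
        return float(max(self.unnormalized_density(np.array(candidates))))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values by rejection from the uniform proposal on [0, 1]."""
        bound = self.density_bound * (1.0 + 1e-12)
        out = np.empty(0)
        while out.size < n:
            block = max(64, 2 * (n - out.size))
            proposal = rng.uniform(size=block)
            accept = rng.uniform(size=block) * bound <= self.unnormalized_density(
                proposal
            )
            out = np.concatenate([out, proposal[accept]])
        return out[:n]


_TARGET_CACHE: dict[tuple[float, float], _MaxEntTarget] = {}


def _maxent_target(mean: float, sd: float) -> _MaxEntTarget:
    key = (float(mean), float(sd))
    if key not in _TARGET_CACHE:
        _TARGET_CACHE[key] = _MaxEntTarget(mean, sd)
    return _TARGET_CACHE[key]


def sample_design(spec: DistributionSpec, n: int, seed: int) -> Design:
    """Generate an ``n``-sample concentration design by rejection sampling.

    Per analyte, values are drawn independently from the maximum-entropy
    density on [minimum, maximum] whose mean and SD equal the spec's printed
    targets, using rejection from a uniform proposal over the range.  Every
    draw respects the bounds by construction, and the design's expected
    sample moments reproduce the spec's moments.

    A degenerate range (minimum == maximum) yields constant samples.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    columns = {}
    for analyte in ANALYTES:
        m = spec.moments(analyte)
        width = m.maximum - m.minimum
        if width == 0.0:
            columns[analyte] = np.full(n, m.minimum)
            continue
        target = _maxent_target((m.mean - m.minimum) / width, m.sd / width)
        columns[analyte] = m.minimum + width * target.sample(n, rng)
    samples = tuple(
        ConcentrationSample(
            glucose=float(columns["glucose"][i]),
            lactate=float(columns["lactate"][i]),
            pyruvate=float(columns["pyruvate"][i]),
        )
        for i in range(n)
    )
    return Design(samples=samples, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum (AU) on a wavenumber grid with acquisition metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    path_length_um: float = REFERENCE_PATH_UM
    n_sweeps_averaged: int = 1
    label: str = ""
    is_artifact: bool = False

    def __post_init__(self) -> None:
        absorbance = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", absorbance)
        if absorbance.shape != (len(self.grid),):
            raise ValueError("absorbance length must match grid length")
        if not np.all(np.isfinite(absorbance)):
            raise ValueError("absorbance must be finite")


def synthesize_spectrum(
    sample: ConcentrationSample,
    library: Sequence[ComponentSpectrum],
    grid: WavenumberGrid | None = None,
    path_length_um: float = REFERENCE_PATH_UM,
    noise_sd: float = 0.0,
    baseline_offset: float = 0.0,
    seed: int | None = None,
    *,
    baseline_slope: float = 0.0,
    response_scale: float = 1.0,
    n_sweeps_averaged: int = 1,
    label: str = "",
) -> Spectrum:
    """Beer-Lambert mixture spectrum of one concentration sample.

    A(nu) = response_scale * (L / 76 um) * sum_i c_i eps_i(nu)
            + baseline_offset + baseline_slope * (nu - nu_mean) + eta(nu),

    with eta ~ Normal(0, noise_sd) i.i.d. per grid point.  ``noise_sd`` is
    the noise of the stored spectrum itself (after any sweep averaging the
    caller accounts for).  ``baseline_slope`` models slow power-envelope
    drift of the source between background and sample acquisition;
    ``response_scale`` models per-measurement effective-response variation
    (gasket compliance, temperature-dependent water-background compensation).
    Both default to their nominal values, so the base model is the plain
    Beer-Lambert mixture; the mixture is exactly linear in concentrations
    and in path-length.
    """
    if path_length_um <= 0:
        raise ValueError("path_length_um must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    grid = grid or WavenumberGrid.default()
    components = library_as_mapping(library)
    for analyte in ANALYTES:
        if getattr(sample, analyte) != 0.0 and analyte not in components:
            raise ValueError(f"analyte {analyte!r} absent from component library")
    nu = grid.values
    absorbance = np.zeros(len(grid))
    for analyte, component in components.items():
        concentration = getattr(sample, analyte, 0.0)
        if concentration:
            absorbance += concentration * component.absorptivity(nu)
    absorbance *= response_scale * (path_length_um / REFERENCE_PATH_UM)
    absorbance += baseline_offset + baseline_slope * (nu - nu.mean())
    if noise_sd > 0:
        absorbance = absorbance + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=len(grid)
        )
    return Spectrum(
        grid=grid,
        absorbance=absorbance,
        path_length_um=path_length_um,
        n_sweeps_averaged=n_sweeps_averaged,
        label=label,
    )


def inject_bubble_artifact(
    spectrum: Spectrum,
    magnitude: float = DEFAULT_BUBBLE_MAGNITUDE,
    seed: int | None = None,
) -> Spectrum:
    """Superimpose a bubble-like distortion and flag the spectrum.

    A bubble transiting the flow-cell scatters the beam, producing a broad
    spurious baseline excursion plus a narrower localized distortion.  The
    excursion is a wide Gaussian (60-120 cm^-1 FWHM) of amplitude
    ``magnitude`` with random sign, the distortion a narrow Gaussian at
    40% amplitude.  ``magnitude = 0`` leaves the absorbance untouched but
    still sets ``is_artifact``.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    nu = spectrum.grid.values
    lo, hi = spectrum.grid.span
    broad_center = rng.uniform(lo, hi)
    broad_fwhm = rng.uniform(60.0, 120.0)
    narrow_center = rng.uniform(lo, hi)
    sign = rng.choice([-1.0, 1.0])
    perturbation = magnitude * sign * PeakModel(
        broad_center, fwhm=broad_fwhm, shape="gaussian"
    ).profile(nu)
    perturbation += 0.4 * magnitude * rng.choice([-1.0, 1.0]) * PeakModel(
        narrow_center, fwhm=6.0, shape="gaussian"
    ).profile(nu)
    return replace(
        spectrum, absorbance=spectrum.absorbance + perturbation, is_artifact=True
    )


def generate_calibration_set(
    design: Design,
    library: Sequence[ComponentSpectrum] | None = None,
    grid: WavenumberGrid | None = None,
    *,
    seed: int,
    noise_sd: float = SWEEP_NOISE_SD,
    n_sweeps: int = DEFAULT_N_SWEEPS,
    offset_sd: float = CAMPAIGN_OFFSET_SD,
    slope_sd: float = CAMPAIGN_SLOPE_SD,
    response_sd: float = CAMPAIGN_RESPONSE_SD,
    n_artifacts: int = 0,
    bubble_magnitude: float = DEFAULT_BUBBLE_MAGNITUDE,
    path_length_um: float = REFERENCE_PATH_UM,
) -> list[Spectrum]:
    """Measure a whole concentration design on the emulated instrument.

    One spectrum per design sample, each the average of ``n_sweeps`` sweeps
    (white noise ``noise_sd / sqrt(n_sweeps)``), with per-measurement
    baseline offset, baseline drift slope and response scale drawn from
    centered normals of the given SDs.  ``n_artifacts`` randomly chosen
    spectra additionally receive a bubble artifact.
    """
    if n_artifacts > len(design):
        raise ValueError("cannot flag more artifacts than spectra")
    library = library if library is not None else default_component_library()
    grid = grid or WavenumberGrid.default()
    rng = np.random.default_rng(seed)
    effective_noise = noise_sd / np.sqrt(n_sweeps)
    spectra: list[Spectrum] = []
    for index, sample in enumerate(design.samples):
        spectra.append(
            synthesize_spectrum(
                sample,
                library,
                grid,
                path_length_um=path_length_um,
                noise_sd=effective_noise,
                baseline_offset=rng.normal(0.0, offset_sd),
                seed=int(rng.integers(2**31)),
                baseline_slope=rng.normal(0.0, slope_sd),
                response_scale=rng.normal(1.0, response_sd),
                n_sweeps_averaged=n_sweeps,
                label=f"S{index + 1:03d}",
            )
        )
    if n_artifacts:
        hit = rng.choice(len(spectra), size=n_artifacts, replace=False)
        for index in hit:
            spectra[index] = inject_bubble_artifact(
                spectra[index], bubble_magnitude, seed=int(rng.integers(2**31))
            )
    return spectra


# ---------------------------------------------------------------------------
# Patient time-series
# ---------------------------------------------------------------------------

#: Per-patient concentration ranges (mM) reported by the bedside analyzer.
PATIENT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "patient1": {
        "glucose": (0.7, 1.7),
        "lactate": (2.1, 9.4),
        "pyruvate": (0.03, 0.10),
    },
    "patient2": {
        "glucose": (1.0, 7.4),
        "lactate": (2.2, 4.7),
        "pyruvate": (0.01, 0.17),
    },
}


@dataclass(frozen=True)
class TimeSeries:
    """Pooled microdialysate monitoring series: references plus spectra."""

    timestamps: np.ndarray
    reference: tuple[ConcentrationSample, ...]
    pooled_from: int
    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        timestamps = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", timestamps)
        object.__setattr__(self, "reference", tuple(self.reference))
        object.__setattr__(self, "spectra", tuple(self.spectra))
        if np.any(np.diff(timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pooled_from not in (3, 4):
            raise ValueError("pooled_from must be 3 or 4")
        if not len(timestamps) == len(self.reference) == len(self.spectra):
            raise ValueError("timestamps, references and spectra must align")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    def reference_matrix(self) -> np.ndarray:
        return np.array([s.as_array() for s in self.reference])


def pool_vials(
    hourly_values: Sequence[ConcentrationSample], k: int
) -> ConcentrationSample:
    """Pool ``k`` consecutive hourly vials (equal volumes -> arithmetic mean)."""
    if k not in (3, 4):
        raise ValueError("k must be 3 or 4")
    if len(hourly_values) != k:
        raise ValueError(f"expected {k} vials, got {len(hourly_values)}")
    mean = np.mean([v.as_array() for v in hourly_values], axis=0)
    return ConcentrationSample(*map(float, mean))


def random_walk_profile(
    ranges: Mapping[str, tuple[float, float]],
    hours: int,
    seed: int,
    smoothness: float = 6.0,
) -> dict[str, Callable[[float], float]]:
    """Smooth random-walk trajectories rescaled into the given per-analyte ranges.

    A standard-normal random walk over the hourly grid is Gaussian-smoothed
    (sigma ``smoothness`` hours) and affinely mapped onto [lo, hi], so the
    trajectory exactly spans and never leaves the stated range.
    """
    rng = np.random.default_rng(seed)
    hour_axis = np.arange(hours, dtype=float)
    profiles: dict[str, Callable[[float], float]] = {}
    for analyte in ANALYTES:
        lo, hi = ranges[analyte]
        walk = gaussian_filter1d(np.cumsum(rng.normal(size=hours)), smoothness)
        spread = walk.max() - walk.min()
        if spread == 0.0 or lo == hi:
            values = np.full(hours, 0.5 * (lo + hi))
        else:
            values = lo + (hi - lo) * (walk - walk.min()) / spread
        profiles[analyte] = _interp1d(hour_axis, values)
    return profiles


def _interp1d(x: np.ndarray, y: np.ndarray) -> Callable[[float], float]:
    return lambda t: float(np.interp(t, x, y))


def generate_patient_series(
    profile: Mapping[str, Callable[[float], float]],
    hours: int,
    pooled_from: int = 3,
    noise_sd: float = SWEEP_NOISE_SD,
    seed: int = 0,
    *,
    library: Sequence[ComponentSpectrum] | None = None,
    grid: WavenumberGrid | None = None,
    n_sweeps: int = DEFAULT_N_SWEEPS,
    offset_sd: float = CAMPAIGN_OFFSET_SD,
    slope_sd: float = CAMPAIGN_SLOPE_SD,
    response_sd: float = CAMPAIGN_RESPONSE_SD,
) -> TimeSeries:
    """Emulate pooled bedside monitoring of one patient.

    Hourly vial concentrations are the profile evaluated at each vial's
    collection midpoint; consecutive windows of ``pooled_from`` vials are
    pooled (arithmetic mean), a trailing incomplete window is dropped, and
    one spectrum is measured per pooled sample with the campaign nuisance
    model.  Timestamps are the pooled windows' midpoints in hours.
    """
    if pooled_from not in (3, 4):
        raise ValueError("pooled_from must be 3 or 4")
    if hours < pooled_from:
        raise ValueError("hours must be at least pooled_from")
    library = library if library is not None else default_component_library()
    grid = grid or WavenumberGrid.default()
    rng = np.random.default_rng(seed)
    hourly = [
        ConcentrationSample(
            **{analyte: max(0.0, profile[analyte](h + 0.5)) for analyte in ANALYTES}
        )
        for h in range(hours)
    ]
    n_pooled = hours // pooled_from
    timestamps, references, spectra = [], [], []
    effective_noise = noise_sd / np.sqrt(n_sweeps)
    for w in range(n_pooled):
        window = hourly[w * pooled_from : (w + 1) * pooled_from]
        pooled = pool_vials(window, pooled_from)
        references.append(pooled)
        timestamps.append((w + 0.5) * pooled_from)
        spectra.append(
            synthesize_spectrum(
                pooled,
                library,
                grid,
                noise_sd=effective_noise,
                baseline_offset=rng.normal(0.0, offset_sd),
                seed=int(rng.integers(2**31)),
                baseline_slope=rng.normal(0.0, slope_sd),
                response_scale=rng.normal(1.0, response_sd),
                n_sweeps_averaged=n_sweeps,
                label=f"P{w + 1:03d}",
            )
        )
    return TimeSeries(
        timestamps=np.array(timestamps),
        reference=tuple(references),
        pooled_from=pooled_from,
        spectra=tuple(spectra),
    )
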