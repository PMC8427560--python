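"""Spectral-conditioning tests: averaging, baseline anchoring, truncation,
differencing, outlier screening and peak heights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdx import preprocess, synthspec
from mirdx.preprocess import (
    average_sweeps,
    baseline_correct,
    first_difference,
    outlier_screen,
    peak_height,
    truncate_range,
)
from mirdx.synthspec import ConcentrationSample, Spectrum, synthesize_spectrum


def make_spectrum(grid, absorbance, **meta):
    return Spectrum(grid=grid, absorbance=np.asarray(absorbance, float), **meta)


class TestAverageSweeps:
    def test_identical_sweeps_unchanged(self, grid):
        sweep = make_spectrum(grid, np.linspace(0, 1, len(grid)))
        averaged = average_sweeps([sweep] * 80)
        assert averaged.absorbance == pytest.approx(sweep.absorbance, rel=1e-14)
        assert averaged.n_sweeps_averaged == 80

    def test_single_spectrum_unchanged(self, grid):
        sweep = make_spectrum(grid, np.ones(len(grid)))
        assert np.array_equal(average_sweeps([sweep]).absorbance, sweep.absorbance)

    def test_noise_reduction_follows_sqrt_n(self, grid):
        """Averaging N pure-noise sweeps shrinks the SD by ~sqrt(N)."""
        rng = np.random.default_rng(0)
        sd, n_sweeps, trials = 1e-3, 16, 100
        ratios = []
        for _ in range(trials):
            sweeps = [
                make_spectrum(grid, rng.normal(0, sd, len(grid)))
                for _ in range(n_sweeps)
            ]
            ratios.append(np.std(average_sweeps(sweeps).absorbance, ddof=1) / sd)
        assert np.mean(ratios) == pytest.approx(1 / np.sqrt(n_sweeps), rel=0.15)

    def test_grid_mismatch_rejected(self, grid):
        other = synthspec.WavenumberGrid(grid.values[:-1], grid.resolution)
        with pytest.raises(ValueError):
            average_sweeps(
                [
                    make_spectrum(grid, np.zeros(len(grid))),
                    make_spectrum(other, np.zeros(len(other))),
                ]
            )


class TestBaselineCorrect:
    def test_constant_offset_removed(self, grid):
        spectrum = make_spectrum(grid, np.full(len(grid), 0.02))
        corrected = baseline_correct(spectrum, anchor=1180.0)
        assert np.all(corrected.absorbance == 0.0)

    def test_idempotent(self, grid, library, mid_sample):
        spectrum = synthesize_spectrum(
            mid_sample, library, grid, baseline_offset=0.005
        )
        once = baseline_correct(spectrum, 1180.0)
        twice = baseline_correct(once, 1180.0)
        assert np.array_equal(once.absorbance, twice.absorbance)

    def test_anchor_outside_span_rejected(self, grid):
        with pytest.raises(ValueError):
            baseline_correct(make_spectrum(grid, np.zeros(len(grid))), 900.0)

    def test_offset_spectrum_recovers_peak_height(self, grid, library, library_map):
        """Correcting at 1180 cancels a baseline offset exactly; the band-tail
        bias at the anchor stays small (Lorentzian tails of the 1152 cm^-1
        glucose band leave ~7% of the 1036 cm^-1 peak at the anchor)."""
        sample = ConcentrationSample(2.0, 0.0, 0.0)
        clean = synthesize_spectrum(sample, library, grid)
        offset = synthesize_spectrum(sample, library, grid, baseline_offset=0.02)
        residual = clean.absorbance[grid.nearest_index(1180.0)]
        peak = clean.absorbance[grid.nearest_index(1036.0)]
        assert abs(residual) < 0.08 * peak
        corrected_offset = baseline_correct(offset, 1180.0)
        corrected_clean = baseline_correct(clean, 1180.0)
        assert corrected_offset.absorbance == pytest.approx(
            corrected_clean.absorbance, abs=1e-15
        )


class TestTruncateRange:
    def test_closed_interval_rule(self, grid):
        spectrum = make_spectrum(grid, np.arange(len(grid), dtype=float))
        kept = truncate_range(spectrum, 1025.0, 1150.0)
        assert kept.grid.values[0] == 1026.0  # smallest grid point >= lo
        assert kept.grid.values[-1] == 1150.0

    def test_full_span_is_identity(self, grid):
        spectrum = make_spectrum(grid, np.arange(len(grid), dtype=float))
        kept = truncate_range(spectrum, 982.0, 1258.0)
        assert np.array_equal(kept.absorbance, spectrum.absorbance)

    def test_truncate_commutes_with_differencing(self, grid, library, mid_sample):
        spectrum = synthesize_spectrum(mid_sample, library, grid)
        diff_then_trunc = first_difference(truncate_range(spectrum, 1025, 1150))
        full_diff = first_difference(spectrum)
        interior = (full_diff.midpoints > 1026.0) & (full_diff.midpoints < 1150.0)
        assert np.allclose(
            diff_then_trunc.differences, full_diff.differences[interior]
        )

    def test_empty_result_rejected(self, grid):
        with pytest.raises(ValueError):
            truncate_range(make_spectrum(grid, np.zeros(len(grid))), 2000.0, 2100.0)


class TestFirstDifference:
    def test_simple_example(self):
        grid = synthspec.WavenumberGrid(np.array([1000.0, 1002.0, 1004.0]), 2.0)
        diffs = first_difference(make_spectrum(grid, [1.0, 2.0, 4.0]))
        assert diffs.differences == pytest.approx([1.0, 2.0])
        assert diffs.midpoints == pytest.approx([1001.0, 1003.0])

    def test_constant_spectrum_is_zero(self, grid):
        diffs = first_difference(make_spectrum(grid, np.full(len(grid), 3.3)))
        assert np.all(diffs.differences == 0.0)

    @settings(max_examples=30, deadline=None)
    @given(offset=st.floats(-1e3, 1e3, allow_nan=False))
    def test_offset_invariance(self, offset):
        grid = synthspec.WavenumberGrid.default()
        rng = np.random.default_rng(42)
        base = rng.normal(size=len(grid))
        d0 = first_difference(make_spectrum(grid, base)).differences
        d1 = first_difference(make_spectrum(grid, base + offset)).differences
        assert np.max(np.abs(d0 - d1)) < 1e-9


class TestOutlierScreen:
    def _campaign(self, seed, n=50, n_artifacts=0):
        design = synthspec.sample_design(
            synthspec.DistributionSpec.default(), n, seed
        )
        return synthspec.generate_calibration_set(
            design, seed=seed, n_artifacts=n_artifacts
        )

    def test_clean_campaigns_unflagged(self):
        for seed in range(20):
            report = outlier_screen(self._campaign(seed))
            assert report.n_flagged == 0

    def test_four_bubbles_in_fifty_exactly_flagged(self):
        """The published protocol: 4 of 50 spectra are artifacts, 46 retained."""
        spectra = self._campaign(123, n=50, n_artifacts=4)
        truth = np.array([s.is_artifact for s in spectra])
        report = outlier_screen(spectra)
        assert np.array_equal(report.flagged, truth)
        assert report.retained_indices().size == 46

    def test_duplicates_never_flagged(self, grid):
        spectrum = make_spectrum(grid, np.linspace(0, 1, len(grid)))
        report = outlier_screen([spectrum] * 10)
        assert report.n_flagged == 0

    def test_too_few_spectra_rejected(self, grid):
        with pytest.raises(ValueError):
            outlier_screen([make_spectrum(grid, np.zeros(len(grid)))] * 2)


class TestPeakHeight:
    def test_zero_spectrum(self, grid):
        assert peak_height(make_spectrum(grid, np.zeros(len(grid))), 1036, 1180) == 0

    def test_recovers_unit_absorptivity(self, grid, library, library_map):
        """1 mM glucose at 76 um reads the configured unit absorptivity up to
        the small anchor-tail bias of single-point baseline correction."""
        spectrum = synthesize_spectrum(
            ConcentrationSample(1.0, 0.0, 0.0), library, grid
        )
        height = peak_height(spectrum, 1036.0, 1180.0)
        assert height == pytest.approx(
            library_map["glucose"].unit_absorptivity, rel=0.08
        )

    def test_linear_in_concentration(self, grid, library):
        heights = [
            peak_height(
                synthesize_spectrum(
                    ConcentrationSample(c, 0.0, 0.0), library, grid
                ),
                1036.0,
                1180.0,
            )
            for c in (1.0, 2.0, 4.0)
        ]
        assert heights[1] == pytest.approx(2 * heights[0], rel=1e-9)
        assert heights[2] == pytest.approx(4 * heights[0], rel=1e-9)
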