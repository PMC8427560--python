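"""Generator unit and property tests: component library, rejection-sampled
designs, Beer-Lambert mixture synthesis, artifacts, pooling and patient
series."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirdx import preprocess, synthspec
from mirdx.synthspec import (
    AnalyteMoments,
    ConcentrationSample,
    DistributionSpec,
    PeakModel,
    WavenumberGrid,
    generate_patient_series,
    inject_bubble_artifact,
    pool_vials,
    random_walk_profile,
    sample_design,
    synthesize_spectrum,
)


class TestGridAndLibrary:
    def test_default_grid_is_instrument_range(self, grid):
        assert len(grid) == 139
        assert grid.span == (982.0, 1258.0)
        assert grid.resolution == 2.0

    def test_grid_rejects_non_monotone(self):
        with pytest.raises(ValueError):
            WavenumberGrid(np.array([1000.0, 998.0, 1002.0]), resolution=2.0)

    def test_band_assignments(self, library_map):
        glucose = {p.center for p in library_map["glucose"].peaks}
        assert {1036.0, 1080.0, 1108.0, 1152.0} <= glucose
        lactate = {p.center for p in library_map["lactate"].peaks}
        assert lactate == {1042.0, 1086.0, 1124.0}
        heights = {p.center: p.relative_height for p in library_map["lactate"].peaks}
        assert heights[1086.0] < heights[1124.0]
        assert [p.center for p in library_map["pyruvate"].peaks] == [1176.0]

    def test_strongest_bands(self, library_map):
        assert library_map["glucose"].strongest_center == 1036.0
        assert library_map["lactate"].strongest_center == 1124.0
        assert library_map["pyruvate"].strongest_center == 1176.0

    def test_absorptivity_nonnegative_and_scaled(self, library_map, grid):
        for component in library_map.values():
            profile = component.absorptivity(grid.values)
            assert np.all(profile >= 0)
            at_strongest = profile[grid.nearest_index(component.strongest_center)]
            assert at_strongest == pytest.approx(component.unit_absorptivity)

    def test_peak_model_validation(self):
        with pytest.raises(ValueError):
            PeakModel(1000.0, fwhm=-1.0)
        with pytest.raises(ValueError):
            PeakModel(1000.0, relative_height=1.5)


class TestSampleDesign:
    def test_degenerate_bounds_yield_constant(self):
        moments = AnalyteMoments(1.0, 0.5, 1.0, 1.0)
        spec = DistributionSpec(glucose=moments, lactate=moments, pyruvate=moments)
        design = sample_design(spec, 5, seed=0)
        for sample in design.samples:
            assert sample.as_array() == pytest.approx([1.0, 1.0, 1.0])

    def test_all_draws_within_bounds(self, design_spec):
        for seed in range(25):
            matrix = sample_design(design_spec, 50, seed).as_matrix()
            for j, analyte in enumerate(synthspec.ANALYTES):
                m = design_spec.moments(analyte)
                assert matrix[:, j].min() >= m.minimum
                assert matrix[:, j].max() <= m.maximum

    def test_moments_match_published_design(self, design_spec):
        """Seed-averaged sample moments reproduce the stated design properties."""
        means = np.zeros(3)
        sds = np.zeros(3)
        n_seeds = 100
        for seed in range(n_seeds):
            matrix = sample_design(design_spec, 50, seed).as_matrix()
            means += matrix.mean(axis=0) / n_seeds
            sds += matrix.std(axis=0, ddof=1) / n_seeds
        targets = [design_spec.moments(a) for a in synthspec.ANALYTES]
        for j, target in enumerate(targets):
            assert means[j] == pytest.approx(target.mean, rel=0.03)
            assert sds[j] == pytest.approx(target.sd, rel=0.05)

    def test_deterministic_given_seed(self, design_spec):
        a = sample_design(design_spec, 20, seed=7)
        b = sample_design(design_spec, 20, seed=7)
        assert np.array_equal(a.as_matrix(), b.as_matrix())
        c = sample_design(design_spec, 20, seed=8)
        assert not np.array_equal(a.as_matrix(), c.as_matrix())

    def test_mean_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            AnalyteMoments(mean=6.0, sd=1.0, minimum=0.0, maximum=5.0)

    def test_infeasible_sd_rejected(self):
        moments = AnalyteMoments(mean=2.5, sd=4.9, minimum=0.0, maximum=5.0)
        spec = DistributionSpec(glucose=moments, lactate=moments, pyruvate=moments)
        with pytest.raises(ValueError, match="infeasible"):
            sample_design(spec, 5, seed=0)


class TestSynthesizeSpectrum:
    def test_empty_mixture_is_zero(self, library, grid):
        blank = ConcentrationSample(0.0, 0.0, 0.0)
        spectrum = synthesize_spectrum(blank, library, grid)
        assert np.all(spectrum.absorbance == 0.0)

    def test_linear_in_concentration(self, library, grid):
        c1 = ConcentrationSample(1.0, 2.0, 0.1)
        c2 = ConcentrationSample(0.5, 1.0, 0.2)
        total = ConcentrationSample(1.5, 3.0, 0.3)
        a = synthesize_spectrum(c1, library, grid).absorbance
        b = synthesize_spectrum(c2, library, grid).absorbance
        c = synthesize_spectrum(total, library, grid).absorbance
        assert np.max(np.abs(a + b - c)) < 1e-12

    def test_path_length_proportionality(self, library, grid, mid_sample):
        full = synthesize_spectrum(mid_sample, library, grid, path_length_um=76.0)
        half = synthesize_spectrum(mid_sample, library, grid, path_length_um=38.0)
        assert np.max(np.abs(full.absorbance - 2.0 * half.absorbance)) < 1e-12

    def test_blank_noise_sd_matches_request(self, library, grid):
        """The sample SD of a noisy blank approaches the requested noise SD."""
        target = 3.0e-4
        blank = ConcentrationSample(0.0, 0.0, 0.0)
        sds = [
            np.std(
                synthesize_spectrum(
                    blank, library, grid, noise_sd=target, seed=seed
                ).absorbance,
                ddof=1,
            )
            for seed in range(100)
        ]
        assert np.mean(sds) == pytest.approx(target, rel=0.10)

    def test_reproducible_given_seed(self, library, grid, mid_sample):
        a = synthesize_spectrum(mid_sample, library, grid, noise_sd=1e-4, seed=3)
        b = synthesize_spectrum(mid_sample, library, grid, noise_sd=1e-4, seed=3)
        assert np.array_equal(a.absorbance, b.absorbance)

    def test_missing_analyte_rejected(self, library, grid):
        partial = [c for c in library if c.analyte != "pyruvate"]
        with pytest.raises(ValueError, match="pyruvate"):
            synthesize_spectrum(
                ConcentrationSample(1.0, 1.0, 0.1), partial, grid
            )


class TestBubbleArtifact:
    def test_zero_magnitude_flags_without_change(self, library, grid, mid_sample):
        clean = synthesize_spectrum(mid_sample, library, grid)
        flagged = inject_bubble_artifact(clean, magnitude=0.0, seed=0)
        assert flagged.is_artifact
        assert np.array_equal(flagged.absorbance, clean.absorbance)

    def test_nonzero_magnitude_perturbs(self, library, grid, mid_sample):
        clean = synthesize_spectrum(mid_sample, library, grid)
        bubbled = inject_bubble_artifact(clean, magnitude=0.05, seed=1)
        assert np.linalg.norm(bubbled.absorbance - clean.absorbance) > 0

    def test_default_artifacts_all_caught_by_screen(self, library, grid, mid_sample):
        """The screen flags every default-magnitude bubble among clean spectra."""
        rng = np.random.default_rng(11)
        spectra = [
            synthesize_spectrum(
                mid_sample, library, grid, noise_sd=3e-5,
                baseline_offset=rng.normal(0, 2e-3),
                seed=int(rng.integers(2**31)),
            )
            for _ in range(40)
        ]
        hit = [3, 17, 25, 31]
        for index in hit:
            spectra[index] = inject_bubble_artifact(
                spectra[index], seed=int(rng.integers(2**31))
            )
        report = preprocess.outlier_screen(spectra)
        assert sorted(np.flatnonzero(report.flagged)) == hit


class TestPoolingAndSeries:
    def test_pooling_is_mean_and_idempotent(self):
        vial = ConcentrationSample(1.0, 2.0, 0.1)
        assert pool_vials([vial] * 3, 3).as_array() == pytest.approx(
            vial.as_array()
        )
        pooled = pool_vials(
            [
                ConcentrationSample(1.0, 2.0, 0.1),
                ConcentrationSample(2.0, 2.0, 0.1),
                ConcentrationSample(3.0, 2.0, 0.1),
            ],
            3,
        )
        assert pooled.glucose == pytest.approx(2.0)

    def test_pooling_permutation_invariant(self):
        vials = [
            ConcentrationSample(0.5, 8.0, 0.05),
            ConcentrationSample(2.5, 3.0, 0.25),
            ConcentrationSample(4.5, 5.5, 0.15),
        ]
        forward = pool_vials(vials, 3)
        backward = pool_vials(vials[::-1], 3)
        assert forward.as_array() == pytest.approx(backward.as_array())

    def test_invalid_pool_size_rejected(self):
        vial = ConcentrationSample(1.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            pool_vials([vial] * 5, 5)

    @pytest.mark.parametrize(
        "hours,pooled_from,expected", [(48, 3, 16), (122, 3, 40)]
    )
    def test_pooled_point_counts(self, hours, pooled_from, expected, library, grid):
        profile = random_walk_profile(
            synthspec.PATIENT_RANGES["patient1"], hours, seed=5
        )
        series = generate_patient_series(
            profile, hours, pooled_from, noise_sd=0.0, seed=5,
            library=library, grid=grid, offset_sd=0.0, slope_sd=0.0,
            response_sd=0.0,
        )
        assert len(series) == expected

    def test_constant_profile_zero_noise(self, library, grid):
        profile = {a: (lambda t, v=v: v) for a, v in
                   zip(synthspec.ANALYTES, (1.2, 3.4, 0.08))}
        series = generate_patient_series(
            profile, 12, 3, noise_sd=0.0, seed=0, library=library, grid=grid,
            offset_sd=0.0, slope_sd=0.0, response_sd=0.0,
        )
        for reference in series.reference:
            assert reference.as_array() == pytest.approx([1.2, 3.4, 0.08])

    def test_profiles_respect_patient_ranges(self):
        for patient, ranges in synthspec.PATIENT_RANGES.items():
            profile = random_walk_profile(ranges, 122, seed=2)
            hours = np.arange(122) + 0.5
            for analyte, (lo, hi) in ranges.items():
                values = np.array([profile[analyte](h) for h in hours])
                assert values.min() >= lo - 1e-12
                assert values.max() <= hi + 1e-12

    def test_series_determinism(self, library, grid):
        profile = random_walk_profile(
            synthspec.PATIENT_RANGES["patient2"], 24, seed=9
        )
        kwargs = dict(library=library, grid=grid)
        a = generate_patient_series(profile, 24, 3, seed=4, **kwargs)
        b = generate_patient_series(profile, 24, 3, seed=4, **kwargs)
        assert np.array_equal(a.timestamps, b.timestamps)
        for s1, s2 in zip(a.spectra, b.spectra):
            assert np.array_equal(s1.absorbance, s2.absorbance)


@settings(max_examples=25, deadline=None)
@given(
    glucose=st.floats(0.02, 5.0),
    lactate=st.floats(0.5, 8.0),
    pyruvate=st.floats(0.02, 0.3),
    scale=st.floats(0.1, 4.0),
)
def test_mixture_scaling_property(glucose, lactate, pyruvate, scale):
    """Scaling all concentrations scales the noise-free spectrum identically."""
    grid = WavenumberGrid.default()
    library = synthspec.default_component_library()
    base = synthesize_spectrum(
        ConcentrationSample(glucose, lactate, pyruvate), library, grid
    ).absorbance
    scaled = synthesize_spectrum(
        ConcentrationSample(glucose * scale, lactate * scale, pyruvate * scale),
        library,
        grid,
    ).absorbance
    assert np.max(np.abs(scaled - scale * base)) < 1e-12
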