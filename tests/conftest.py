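import numpy as np
import pytest

from mirdx import synthspec
from mirdx.synthspec import (
    ConcentrationSample,
    DistributionSpec,
    WavenumberGrid,
    default_component_library,
)


@pytest.fixture(scope="session")
def grid() -> WavenumberGrid:
    return WavenumberGrid.default()


@pytest.fixture(scope="session")
def library():
    return default_component_library()


@pytest.fixture(scope="session")
def library_map(library):
    return synthspec.library_as_mapping(library)


@pytest.fixture(scope="session")
def design_spec() -> DistributionSpec:
    return DistributionSpec.default()


@pytest.fixture()
def mid_sample() -> ConcentrationSample:
    """A sample near the middle of each analyte's physiological range."""
    return ConcentrationSample(glucose=2.0, lactate=4.0, pyruvate=0.15)


def make_component_matrix(library, grid, lo=None, hi=None, differenced=False):
    """Component absorptivity profiles as rows, optionally truncated/differenced."""
    from mirdx import preprocess

    rows = []
    for component in library:
        values = component.absorptivity(grid.values)
        spectrum = synthspec.Spectrum(grid=grid, absorbance=values)
        if lo is not None:
            spectrum = preprocess.truncate_range(spectrum, lo, hi)
        rows.append(
            preprocess.first_difference(spectrum).differences
            if differenced
            else spectrum.absorbance
        )
    return np.array(rows)
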