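import numpy as np
import pytest

from carofret import GroundTruth, TimeGrid, simulate_polarized_decays

#: packaged two-component fixture: a fast FRET-quenched donor population
#: (82% at 1.45 ns) plus an unquenched one (18% at 5.601 ns), single
#: rotational correlation time 2 ns, detector bias 1.2, 5e6 counts/geometry
TWO_COMPONENT_TRUTH = dict(
    intensity_components=[(0.82, 1.45), (0.18, 5.601)],
    anisotropy_r0=0.35,
    anisotropy_components=[(1.0, 2.0)],
    g_true=1.2,
    total_counts=5e6,
    irf_fwhm=0.1,
)

TWO_COMPONENT_GRID = TimeGrid(0.0, 30.0, 4096)


@pytest.fixture
def two_component_truth():
    return GroundTruth(**TWO_COMPONENT_TRUTH, seed=7)


@pytest.fixture
def two_component_decays(two_component_truth):
    return simulate_polarized_decays(two_component_truth, TWO_COMPONENT_GRID)


@pytest.fixture
def noise_free_mono():
    """Noise-free single-lifetime, single-theta decays with a delta IRF."""
    truth = GroundTruth(
        intensity_components=[(1.0, 5.601)],
        anisotropy_r0=0.35,
        anisotropy_components=[(1.0, 2.0)],
        g_true=1.1,
        total_counts=5e6,
        irf_fwhm=0.0,
        seed=42,
    )
    grid = TimeGrid(0.0, 50.0, 4096)
    return truth, simulate_polarized_decays(truth, grid, noise=False)
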