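import numpy as np
import pytest

from kiwitrts.instrument import DEFAULT_GRID, TimeResolvedProfile, make_gaussian_irf
from kiwitrts.forward_model import OpticalProperties, SlabGeometry, transmittance_curve
from kiwitrts.instrument import convolve_with_irf
from kiwitrts.synthetic_data import StudyConfig, generate_study


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def irf(grid):
    return make_gaussian_irf(grid, fwhm=159.83, center=200.0)


@pytest.fixture(scope="session")
def noiseless_trp(grid, irf):
    """Forward-rendered TRP at known optics (mu_a=0.010, mu_s'=0.60, s=51)."""
    truth = OpticalProperties(0.010, 0.60)
    geom = SlabGeometry(51.0)
    curve = transmittance_curve(grid.times, truth, geom)
    expected = convolve_with_irf(curve, irf, grid)
    counts = expected * (1e6 / expected.sum())
    trp = TimeResolvedProfile(grid, counts, {"sample_id": "syn-01", "day": 0})
    return trp, truth, geom


@pytest.fixture(scope="session")
def small_study():
    """Reduced study (4 fruit per arm, 1e5 counts) for fast integration tests."""
    cfg = StudyConfig(n_samples=4, total_counts=1e5, seed=7)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """The reference study conditions at the package default seed."""
    return generate_study(StudyConfig())
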