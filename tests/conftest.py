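import numpy as np
import pytest

from dogcsf import BASE_PARAMS, make_grid, make_sweep, run_csf


@pytest.fixture(scope="session")
def grid():
    """Default 4000-sample, 10-degree grid."""
    return make_grid()


@pytest.fixture(scope="session")
def sweep():
    """Default 200-point logarithmic sweep, 0.1-100 cpd."""
    return make_sweep()


@pytest.fixture(scope="session")
def base_curve(grid, sweep):
    """Base-condition sensitivity curve, shared across tests."""
    return run_csf(BASE_PARAMS, sweep, grid)


@pytest.fixture(scope="session")
def coarse_grid():
    """Cheaper grid for tests that do not need full resolution."""
    return make_grid(1000, 10.0)


def analysis_mask(freqs, f_max=25.0):
    return (freqs >= 0.1) & (freqs <= f_max)


@pytest.fixture(scope="session")
def analysis(base_curve):
    """Boolean mask of the analyzed 0.1-25 cpd range on the default sweep."""
    return analysis_mask(base_curve.frequencies_cpd)
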