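import warnings

import numpy as np
import pytest

from quenchfp import CovarianceSpec, sample_gaussian


def pytest_configure(config):
    # solver warnings about expansion validity etc. are expected in tests
    warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def brownian_ensemble():
    """Shared Brownian ensemble (H = 1/2 quench, exactly min(t, t'))."""
    spec = CovarianceSpec(H=0.5, kind="quench", T=0.0)
    grid = np.geomspace(0.02, 2000.0, 500)
    return sample_gaussian(spec, grid, n=8000, seed=101), spec


@pytest.fixture(scope="session")
def fbm_ensemble():
    """Shared stationary fBM ensemble, H = 0.375."""
    spec = CovarianceSpec(H=0.375, kind="stationary")
    grid = np.geomspace(0.02, 2000.0, 500)
    return sample_gaussian(spec, grid, n=8000, seed=102), spec
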