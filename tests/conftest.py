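import numpy as np
import pytest

import hytrait as ht


@pytest.fixture(scope="session")
def coarse_grid():
    """Desk-scale instrument grid: 40 nm bands over 400-2500 nm (53 bands)."""
    return ht.build_band_grid(400, 2500, 40, 40, "coarse40")


@pytest.fixture(scope="session")
def small_pool(coarse_grid):
    """Simulated pool on the coarse grid: fine-grid simulation, Gaussian SRF
    resampling, default exclusion windows applied."""
    from hytrait.workflow import build_pool

    return build_pool(n=400, grid=coarse_grid, seed=11, fine_step=5)


@pytest.fixture(scope="session")
def default_library():
    """Library simulated directly on the default 10 nm grid (no exclusions)."""
    return ht.generate_library(n=200, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
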