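import numpy as np
import pytest

from drcsi.grids import (
    build_kernel,
    build_spectral_grid,
    default_acquisition,
)


@pytest.fixture(scope="session")
def acq():
    return default_acquisition()


@pytest.fixture(scope="session")
def grid():
    return build_spectral_grid()


@pytest.fixture(scope="session")
def kernel(acq, grid):
    return build_kernel(acq, grid)


@pytest.fixture(scope="session")
def small_kernel(acq):
    """5×5 spectral grid kernel for oracle-equivalence and speed-bound tests."""
    g = build_spectral_grid(5, 5)
    return build_kernel(acq, g)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
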