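import warnings

import numpy as np
import pytest

import funbayes as fb

warnings.filterwarnings("ignore", category=RuntimeWarning)
np.seterr(all="ignore")


@pytest.fixture(scope="session")
def grid():
    return fb.default_grid(50)


@pytest.fixture(scope="session")
def basis(grid):
    return fb.build_penalized_basis(grid, K=10)


@pytest.fixture(scope="session")
def centered_basis(grid):
    return fb.build_penalized_basis(grid, K=10, center=True)


@pytest.fixture(scope="session")
def sofr_data():
    return fb.simulate_sofr(fb.DGPConfig(n=60, tau=2, seed=42, holdout=10))


@pytest.fixture(scope="session")
def survival_data():
    return fb.simulate_survival(fb.DGPConfig(n=50, tau=2, seed=43, holdout=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
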