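import numpy as np
import pytest

from ncrm import (BaseDistribution, DoseGrid, DPPrior, SamplerConfig,
                  TrialState, builtin_scenarios)


@pytest.fixture(scope="session")
def grid8():
    return DoseGrid(np.arange(1, 9, dtype=float), theta=0.3)


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


@pytest.fixture(scope="session")
def base62():
    return BaseDistribution(6.0, 2.0)


@pytest.fixture(scope="session")
def fast_sampler():
    """Short chain for mechanics tests where only dynamics matter."""
    return SamplerConfig(n_burnin=100, n_keep=150)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180604)


def make_trial(n, y, K=8):
    nn = np.zeros(K, dtype=np.int64)
    yy = np.zeros(K, dtype=np.int64)
    nn[: len(n)] = n
    yy[: len(y)] = y
    return TrialState(nn, yy)


@pytest.fixture(scope="session")
def table2_trial():
    """The worked single-trial dataset: n=(6,3,3,9,33,6), y=(1,0,1,0,10,4)."""
    return make_trial([6, 3, 3, 9, 33, 6], [1, 0, 1, 0, 10, 4])
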