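import warnings

import numpy as np
import pytest
from sklearn.exceptions import ConvergenceWarning

from txtwas.fitters import FitterConfig
from txtwas.simulate import SimConfig, simulate_locus


@pytest.fixture(autouse=True)
def _quiet_sklearn():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small, strongly heritable locus for fast fitter checks."""
    return SimConfig(
        n_train=300, p_snps=50, m_isoforms=3, p_causal=0.05, p_shared=1.0,
        h_g2=0.25, sigma_h=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def small_locus(small_config):
    return simulate_locus(small_config)


@pytest.fixture(scope="session")
def fast_cfg() -> FitterConfig:
    return FitterConfig.fast(seed=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
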