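import warnings

import numpy as np
import pytest

from dwellkin import ComplexConfig, RateParams


def quiet_params(x: float, y: float, u: float) -> RateParams:
    """RateParams without the sub-unity-parameter warning (for random sweeps)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RateParams(x, y, u)


@pytest.fixture(scope="session")
def fitted_params() -> RateParams:
    """The published fitted parameter triple."""
    return RateParams(x=1.7, y=5.0, u=4.6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230606)


@pytest.fixture
def ss_config() -> ComplexConfig:
    return ComplexConfig("ss", 23, 23)


@pytest.fixture
def nn_config() -> ComplexConfig:
    return ComplexConfig("nn", 23, 23)


@pytest.fixture
def ns_config() -> ComplexConfig:
    return ComplexConfig("ns", 23, 23)
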