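import numpy as np
import pytest

from pkdeconv import PKParameters
from pkdeconv.input_prior import build_kl_basis
from pkdeconv.synthetic_data import TestInputParams, SHORT_T_END_MIN


@pytest.fixture(scope="session")
def pk_params():
    return PKParameters()


@pytest.fixture(scope="session")
def input_params():
    return TestInputParams()


@pytest.fixture(scope="session")
def short_basis():
    """A coarse short-timescale basis: cheap enough for ODE-based tests."""
    return build_kl_basis(30.0, SHORT_T_END_MIN, n_grid=100, n_basis=12)


@pytest.fixture(scope="session")
def long_basis():
    from pkdeconv.synthetic_data import LONG_T_END_MIN

    return build_kl_basis(1209.6, LONG_T_END_MIN, n_grid=200, n_basis=20)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170419)
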