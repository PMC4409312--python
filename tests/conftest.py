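import numpy as np
import pytest

from fluctmod.models import ELIFParams, PassiveLIFParams, HHParams
from fluctmod.noise import calibrate_noise_coefficient


@pytest.fixture(scope="session")
def elif15():
    return ELIFParams(Delta_T=15.0)


@pytest.fixture(scope="session")
def elif2():
    return ELIFParams(Delta_T=2.0)


@pytest.fixture(scope="session")
def passive():
    return PassiveLIFParams()


@pytest.fixture(scope="session")
def hh():
    return HHParams()


@pytest.fixture(scope="session")
def coeff15(elif15):
    """Calibrated noise coefficient for the Delta_T = 15 mV cell."""
    return calibrate_noise_coefficient(elif15, seed=101)


@pytest.fixture(scope="session")
def coeff2(elif2):
    return calibrate_noise_coefficient(elif2, seed=102)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
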