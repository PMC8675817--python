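import numpy as np
import pytest

from mapmpc.patient_model import (
    ContinuousPatientModel,
    canonical_model,
    discretize_zoh,
)


@pytest.fixture(scope="session")
def canonical():
    return canonical_model()


@pytest.fixture(scope="session")
def dcanon(canonical):
    return discretize_zoh(canonical, 1.0)


@pytest.fixture(scope="session")
def toy_lag_discrete():
    """Delay-free first-order lag 1/(1+5s) at Ts=1: fast closed-loop testbed."""
    lag = ContinuousPatientModel(num=(1.0,), den=(5.0, 1.0), dead_time=0.0)
    return discretize_zoh(lag, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
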