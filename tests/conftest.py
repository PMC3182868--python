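import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import il21pkpd as il

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sc_model():
    """Default B16-early model with SC administration."""
    return il.default_model("SC", "B16-early")


@pytest.fixture(scope="session")
def iv_setup():
    return il.default_topology("IV"), il.default_pk_params("IV")


@pytest.fixture(scope="session")
def std_regimen():
    return il.standard_b16_regimen()


@pytest.fixture(scope="session")
def pbs_regimen(std_regimen):
    return std_regimen.replace(dose_ug=0.0, n_doses=0, label="PBS")


@pytest.fixture(scope="session")
def std_trajectory(sc_model, std_regimen):
    """Standard 50 µg/day SC therapy simulated to day 20 (shared)."""
    return sc_model.simulate(std_regimen, t_end=20.0, dt=0.002)


@pytest.fixture(scope="session")
def pbs_trajectory(sc_model, pbs_regimen):
    return sc_model.simulate(pbs_regimen, t_end=20.0, dt=0.002)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
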