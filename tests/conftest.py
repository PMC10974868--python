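import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gispbbm import io

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PRODUCTS = io.PRODUCTS


@pytest.fixture(scope="session")
def invitro_scenarios():
    return {p: io.packaged_scenario("in_vitro", p) for p in PRODUCTS}


@pytest.fixture(scope="session")
def invivo_scenarios():
    return {p: io.packaged_scenario("in_vivo", p) for p in PRODUCTS}


@pytest.fixture(scope="session")
def codiovan_invitro(invitro_scenarios):
    return invitro_scenarios["CoDiovan"]


@pytest.fixture(scope="session")
def codiovan_invivo(invivo_scenarios):
    return invivo_scenarios["CoDiovan"]


@pytest.fixture(scope="session")
def pk_params(codiovan_invivo):
    return codiovan_invivo.pk


@pytest.fixture(scope="session")
def coarse_times():
    return np.arange(0.0, 240.0 + 1e-9, 10.0)
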