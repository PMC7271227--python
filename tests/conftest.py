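import pytest
from hypothesis import HealthCheck, settings

import biasfront as bf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def khoikhoi():
    return bf.builtin_case("khoikhoi")


@pytest.fixture(scope="session")
def bantu():
    return bf.builtin_case("bantu")


@pytest.fixture(scope="session")
def herder_kernel(khoikhoi):
    return khoikhoi.kernel


@pytest.fixture(scope="session")
def farmer_kernel(bantu):
    return bantu.kernel


@pytest.fixture(scope="session")
def fast_demog():
    """Upper-curve demographic extreme shared by both case studies."""
    return bf.Demography(a=0.033, T=29.0)


@pytest.fixture(scope="session")
def slow_demog():
    return bf.Demography(a=0.023, T=35.0)
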