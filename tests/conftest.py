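import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import HealthCheck, settings

import robmeta as rm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tzd() -> rm.EffectSet:
    return rm.load_fixture("tzd_effects")


@pytest.fixture(scope="session")
def cox2() -> rm.EffectSet:
    return rm.load_fixture("cox2_effects")


@pytest.fixture(scope="session")
def tzd_rob() -> list[rm.RoBProfile]:
    return rm.load_fixture("tzd_rob")


@pytest.fixture(scope="session")
def cox2_rob() -> list[rm.RoBProfile]:
    return rm.load_fixture("cox2_rob")


@pytest.fixture(scope="session")
def tzd_mi(tzd) -> rm.EffectSet:
    return tzd.select(outcome="myocardial_infarction")


@pytest.fixture(scope="session")
def ibuprofen(cox2) -> rm.EffectSet:
    return cox2.select(exposure="ibuprofen")
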