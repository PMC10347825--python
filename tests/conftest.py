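import pytest
from hypothesis import HealthCheck, settings

from eplscore import published_system

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def system():
    return published_system()[0]


@pytest.fixture(scope="session")
def risk_table():
    return published_system()[1]
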