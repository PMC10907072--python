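import pytest
from hypothesis import HealthCheck, settings

from cvloop import CirculationParameters
from cvloop.config import default_muscle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> CirculationParameters:
    """Default (rat-scale) circulation parameter set."""
    return CirculationParameters()


@pytest.fixture(scope="session")
def muscle(params):
    """Reference virtual trabecula matched to the circulation geometry."""
    return default_muscle(params)
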