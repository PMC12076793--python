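import pytest
from hypothesis import HealthCheck, settings

from microcea import baseline_parameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def baseline():
    """A fresh copy of the bundled adult baseline parameters."""
    return baseline_parameters("adult")


@pytest.fixture
def baseline_under4():
    return baseline_parameters("under4")
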