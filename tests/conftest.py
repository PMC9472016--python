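import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from spiralsort import get_preset  # noqa: E402


@pytest.fixture(scope="session")
def wb1():
    """Original trifurcated design, calibrated at its 860 ul/min working point."""
    return get_preset("WB1")


@pytest.fixture(scope="session")
def wb1r():
    """Redesigned bifurcated device (widened 500 um outlet section), 940 ul/min."""
    return get_preset("WB1r")
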