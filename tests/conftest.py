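import pytest
from hypothesis import HealthCheck, settings

from tfg.geometry import VectorDesign

settings.register_profile(
    "suite",
    max_examples=100,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ade6_design() -> VectorDesign:
    """The asymmetric-arm design used throughout: 2500/1659/800, DSB at 4559."""
    return VectorDesign.ade6()
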