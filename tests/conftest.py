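import pytest
from hypothesis import HealthCheck, settings

from seedchain import MapParams

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def params() -> MapParams:
    return MapParams()
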