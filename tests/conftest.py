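import pytest
from hypothesis import HealthCheck, settings

from synaptrace.fragments import fragment_r100, fragment_r250

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def frag250():
    return fragment_r250()


@pytest.fixture(scope="session")
def frag100():
    return fragment_r100()
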