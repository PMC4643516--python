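import pytest
from hypothesis import HealthCheck, settings

from echotex import compile_matcher
from echotex.synthetic import build_fixture_terminology

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def terminology():
    return build_fixture_terminology()


@pytest.fixture(scope="session")
def matcher(terminology):
    return compile_matcher(terminology)
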