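import pytest
from hypothesis import HealthCheck, settings

from anthonet.annotate import AnnotationParams
from anthonet.masscalc import default_library

settings.register_profile(
    "fixed",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def params():
    return AnnotationParams()
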