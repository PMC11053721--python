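import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dentaltrueness import build_model, default_spec, enumerate_feature_sizes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def spec_max():
    return default_spec("maxillary")


@pytest.fixture(scope="session")
def spec_mand():
    return default_spec("mandibular")


@pytest.fixture(scope="session")
def ref_max(spec_max):
    """Default-resolution maxillary reference mesh."""
    return build_model(spec_max)


@pytest.fixture(scope="session")
def ref_mand(spec_mand):
    return build_model(spec_mand)


@pytest.fixture(scope="session")
def ref_max_coarse(spec_max):
    """Coarser mesh for registration-heavy tests (metrics stay exact)."""
    return build_model(spec_max, patch_mm=3.0)


@pytest.fixture(scope="session")
def schema(spec_max, spec_mand):
    return enumerate_feature_sizes(spec_max, spec_mand)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240412)
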