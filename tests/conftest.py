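import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emtquad import default_params
from emtquad.steady import archetype_states

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Reconstructed basal parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def green_params(params):
    """Basal parameters at the intermediate TGF-β working point where
    all four phenotypes coexist."""
    return params.replace(tgfb_exo=0.5)


@pytest.fixture(scope="session")
def reference(params):
    """E/I1/I2/M archetype states from the tetra-stable condition."""
    return archetype_states(params, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
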