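import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One full synthetic study bundle shared across tests."""
    from sodkit.synthetic import generate_bundle

    out = tmp_path_factory.mktemp("bundle")
    truth = generate_bundle(11, out)
    return out, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
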