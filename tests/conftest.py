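import numpy as np
import pytest
from hypothesis import settings

from runtumble import estimate_true_model

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def true_model():
    """Moderate-size random-policy reference model, shared across tests."""
    return estimate_true_model(n_samples=200_000, seed=7)
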