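import numpy as np
import pytest
from hypothesis import settings

from liprot.fixtures import FixtureSpec, make_membrane_system

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def membrane_system():
    """Small jittering bilayer + protein cylinder used across tests."""
    return make_membrane_system(
        FixtureSpec(seed=7, n_frames=5, motion="gaussian", jitter_sigma=0.05)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
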