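import numpy as np
import pytest

from statewell.config import FISH_A, FISH_B
from statewell.latent import LatentTrajectory
from statewell.potential import LatentMap


@pytest.fixture(scope="session")
def fish_a():
    return FISH_A


@pytest.fixture(scope="session")
def fish_b():
    return FISH_B


@pytest.fixture
def constant_latent():
    """A flat latent trajectory (any value; maps are anchored separately)."""

    def make(value=0.0, duration=1e5):
        return LatentTrajectory(
            t=np.array([0.0, duration]), s=np.array([value, value])
        )

    return make


@pytest.fixture
def symmetric_map_a():
    """Latent map frozen at the symmetric Fish A well (a=0, d=0.3)."""
    return LatentMap(s_min=0.0, s_max=1.0, a1=0.0, a2=0.0, d1=0.3, d2=0.3)
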