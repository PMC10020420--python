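import numpy as np
import pytest

from selfishherd.environment import HerdFrame, init_episode


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_frame(rng) -> HerdFrame:
    """20 non-overlapping agents scattered in a 15-sigma box."""
    return init_episode(20, 15.0, rng)
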