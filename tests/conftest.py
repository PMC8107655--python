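import numpy as np
import pytest

from plmotion import (
    BIRD_SPEC,
    HUMAN_SPEC,
    generate_bird_trajectory,
    generate_walker_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bird():
    return generate_bird_trajectory(BIRD_SPEC, np.random.default_rng(7))


@pytest.fixture(scope="session")
def walker():
    return generate_walker_trajectory(HUMAN_SPEC, np.random.default_rng(7))
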