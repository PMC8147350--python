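import numpy as np
import pytest
from hypothesis import settings

import stingsim as ss

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def encoder() -> ss.PerceptEncoder:
    return ss.PerceptEncoder()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_forced_memory(
    n_percepts: int = 10,
    p_pheromone: float = 0.5,
    p_v_esc: float = 0.5,
) -> ss.Memory:
    """Memory whose stinging probabilities are (approximately) forced.

    Probabilities 0 and 1 are realised with a 1e12 counterweight, which is
    exact to ~1e-12 — far below any tolerance used in the tests.
    """

    def row(p: float) -> tuple[float, float]:
        if p <= 0.0:
            return (1e12, 1.0)
        if p >= 1.0:
            return (1.0, 1e12)
        if p >= 0.5:
            return (1.0, p / (1.0 - p))
        return ((1.0 - p) / p, 1.0)

    h = np.array([row(p_pheromone)] * (n_percepts - 1) + [row(p_v_esc)])
    return ss.Memory(h)


@pytest.fixture
def forced_memory():
    return make_forced_memory
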