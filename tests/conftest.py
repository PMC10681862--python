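import numpy as np
import pytest

from gmcoda import (
    BlockStructure,
    compute_moments,
    draw_mean,
    make_random,
    simulate,
)


@pytest.fixture
def two_blocks():
    return BlockStructure((2, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A d=2 dataset simulated from a known sparse truth (p=20, n=200)."""
    structure = BlockStructure((10, 10))
    ss = np.random.SeedSequence(42)
    s1, s2, s3 = ss.spawn(3)
    truth = make_random(20, np.random.default_rng(s1), structure=structure)
    mean = draw_mean(20, np.random.default_rng(s2))
    sim = simulate(truth, mean, 200, np.random.default_rng(s3))
    return sim


@pytest.fixture(scope="session")
def small_moments(small_sim):
    return compute_moments(small_sim.data)
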