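import numpy as np
import pytest
from hypothesis import settings

from g4bulge.simulate import build_planted_genome, simulate_genome

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_planted():
    """A 100 kb genome with 30 planted motifs (all six models), session-wide."""
    genome, truth = build_planted_genome(
        length=100_000, n_motifs=30, seed=424242
    )
    return genome, truth


@pytest.fixture(scope="session")
def background_genome():
    return simulate_genome(2, 50_000, gc_fraction=0.4, seed=77)


def random_dna(rng, length, g_prob=0.35):
    """Random test string with elevated guanine content."""
    other = (1 - g_prob) / 3
    return "".join(
        rng.choice(list("ACGT"), size=length, p=[other, other, g_prob, other])
    )
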