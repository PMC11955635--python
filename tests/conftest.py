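import numpy as np
import pytest

from tcrsift import SimulationConfig, toy_library
from tcrsift.repertoire import ReadPair, revcomp


@pytest.fixture(scope="session")
def library():
    return toy_library()


@pytest.fixture(scope="session")
def small_cfg():
    """Small repertoire for fast read-level tests."""
    return SimulationConfig(seed=11, n_background_clonotypes=50,
                            reads_per_sample=1000)


def make_pair(seq1, seq2, qual1=None, qual2=None, pair_id="p"):
    qual1 = tuple(qual1) if qual1 is not None else (30,) * len(seq1)
    qual2 = tuple(qual2) if qual2 is not None else (30,) * len(seq2)
    return ReadPair(pair_id, seq1, seq2, qual1, qual2)


def overlapping_pair(fragment, read_len, qual1=None, qual2=None):
    """Mates covering the two ends of ``fragment`` (mate2 as sequenced)."""
    return make_pair(fragment[:read_len], revcomp(fragment[-read_len:]),
                     qual1, qual2)


def random_fragment(rng, n):
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
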