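import numpy as np
import pytest

from seqppi import SignalSpec, encode_pairs, gen_pairs, gen_proteome
from seqppi.features import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def make_sequence(rng):
    return lambda length: random_sequence(rng, length)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-signal dataset shared across tests.

    60+60 pairs, full signal, short sequences: enough for the pipeline
    to separate classes while keeping encoding cheap.
    """
    rng = np.random.default_rng(7)
    spec = SignalSpec(length_range=(50, 90))
    proteome = gen_proteome(240, spec, rng)
    pairs, proteome, motifs = gen_pairs(proteome, 60, 60, spec, rng)
    return proteome, pairs, motifs


@pytest.fixture(scope="session")
def small_benchmark_features(small_benchmark):
    proteome, pairs, _ = small_benchmark
    X, y = encode_pairs(proteome, pairs)
    return X, y
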