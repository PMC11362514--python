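import numpy as np
import pytest

from rngbench import Sequence, SequenceSet
from rngbench.complexity import synthetic_ctm_table
from rngbench.simulate import GeneratorSpec, generate_uniform


def make_seq(values, a=9, id=""):
    return Sequence(np.asarray(values), alphabet_size=a, id=id)


@pytest.fixture(scope="session")
def random_short_sequences():
    """100 random sequences of lengths 5-50 for oracle cross-checks."""
    rng = np.random.default_rng(20240917)
    seqs = []
    for i in range(100):
        length = int(rng.integers(5, 51))
        values = rng.integers(1, 10, size=length)
        seqs.append(Sequence(values, alphabet_size=9, id=f"s{i}"))
    return seqs


@pytest.fixture(scope="session")
def uniform_pop():
    """1000 i.i.d. uniform sequences of study dimensions (L=200, a=9)."""
    return generate_uniform(GeneratorSpec(n=1000, length=200, seed=101))


@pytest.fixture(scope="session")
def small_ctm_table(random_short_sequences):
    """Synthetic complexity table covering the short-sequence fixtures."""
    return synthetic_ctm_table(
        random_short_sequences, block_lengths=range(2, 11), alphabet_size=9
    )
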