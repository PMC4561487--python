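import numpy as np
import pytest

from motifenv.pfm import PFM, Background
from motifenv.simulate import random_pfm


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def sharp_pfm():
    """Informative 8-bp non-palindromic motif used across tests."""
    return random_pfm(length=8, ic_per_column=1.5, gc_target=0.5, seed=11)


@pytest.fixture(scope="session")
def small_pfm():
    """Short motif (L=5) for enumeration-based oracles."""
    rng = np.random.default_rng(3)
    freq = rng.dirichlet(np.full(4, 0.8), size=5)
    return PFM(name="rand5", freq=freq)


@pytest.fixture(scope="session")
def palindromic_pfm():
    """Motif equal to its own reverse complement (consensus ACGCGT)."""
    eps = 0.06
    cons = [0, 1, 2, 1, 2, 3]  # A C G C G T
    freq = np.full((6, 4), eps / 3.0)
    for i, b in enumerate(cons):
        freq[i, b] = 1.0 - eps
    return PFM(name="pal", freq=freq)


def random_sequences(n, length, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return [
        (f"s{i}", "".join(rng.choice(bases, size=length, p=probs)))
        for i in range(n)
    ]
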