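import numpy as np
import pytest

from spatialdiv.alignment import Alignment


@pytest.fixture
def toy_three():
    """The three maximally diverged toy sequences."""
    return Alignment.from_sequences(["AAA", "GGG", "TTT"])


@pytest.fixture
def toy_four():
    """The toy population with a duplicated haplotype."""
    return Alignment.from_sequences(["AAA", "GGG", "TTT", "GGG"])


@pytest.fixture
def random_population():
    """A factory for small random populations (for enumeration checks)."""

    def make(n: int, length: int, seed: int, alphabet: str = "ACGT") -> Alignment:
        rng = np.random.default_rng(seed)
        letters = np.array(list(alphabet))
        seqs = ["".join(rng.choice(letters, size=length)) for _ in range(n)]
        return Alignment.from_sequences(seqs)

    return make
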