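import numpy as np
import pytest

from aggprop.core_io import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peptide(rng, length):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture
def make_peptide(rng):
    def _make(length=None):
        if length is None:
            length = int(rng.integers(31, 201))
        return random_peptide(rng, length)

    return _make
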