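import numpy as np
import pytest

from svk.digest import load_enzyme_table
from svk.io import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def enzymes():
    return load_enzyme_table()


@pytest.fixture(scope="session")
def bsli(enzymes):
    return enzymes["BslI"]


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def dna_record(rng):
    def make(length=100, seq_id="seq"):
        return SequenceRecord(seq_id, random_dna(rng, length))

    return make
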