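import numpy as np
import pytest

from famscan.cis_regulation import load_catalog
from famscan.io_formats import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


def record(ident, seq, desc=""):
    return SequenceRecord(ident, seq, desc)
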