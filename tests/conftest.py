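import numpy as np
import pytest

from msaforge.seq_core import Sequence, SubstitutionMatrix
from msaforge.similarity import default_hmm_params

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def hmm_params():
    return default_hmm_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230713)


def random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


@pytest.fixture(scope="session")
def toy_family():
    """Three short sequences whose pairwise alignments are unambiguous."""
    return [
        Sequence("a", "MKVLITAGHE"),
        Sequence("b", "MKVLTAGHE"),
        Sequence("c", "MKVLITAGWE"),
    ]
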