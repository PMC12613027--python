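import random

import pytest

from lysocleave.encoders import AA_ALPHABET, AnnotatedSequence


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA_ALPHABET) for _ in range(length))


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def peptide():
    return AnnotatedSequence(id="pep", residues="PEPTIDE")


@pytest.fixture
def carrier():
    """The worked positive window TVVLFKKF embedded at p1=7 (P1 = L)."""
    return AnnotatedSequence(id="carrier", residues="AAA" + "TVVLFKKF" + "GGG")
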