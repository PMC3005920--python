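import pytest

from epibayes.datasets_io import Peptide, PeptidePool


def pool(*seqs: str, label: str = "unlabeled") -> PeptidePool:
    return PeptidePool([Peptide(s, label) for s in seqs])


@pytest.fixture
def tiny_pos():
    return pool("AC", "AC", label="positive")


@pytest.fixture
def tiny_neg():
    return pool("AC", "GC", label="negative")
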