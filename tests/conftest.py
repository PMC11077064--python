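import pytest
from hypothesis import settings

from comphom import IDR_COMPOSITION, FamilySpec, SequenceRecord, make_family

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_fasta(tmp_path):
    """Three short canonical records on disk."""
    path = tmp_path / "toy.fasta"
    path.write_text(">a\nMKRHHG\n>b\nDDEEKK\n>c\nSPTPAR\n")
    return path


@pytest.fixture
def idr_family():
    """Six 1500-mers sharing the disordered-region composition preset."""
    return make_family(FamilySpec(IDR_COMPOSITION, 6, (1500, 1500), seed=11))


@pytest.fixture
def rec():
    def _make(residues, ident="x"):
        return SequenceRecord(ident, residues)

    return _make
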