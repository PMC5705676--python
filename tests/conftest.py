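import pytest

from proteotrim import ProteinRecord, Proteome


def make_proteome(species: str, sequences: dict[str, str]) -> Proteome:
    return Proteome(
        species,
        [
            ProteinRecord(pid, f"test protein {pid}", seq, species)
            for pid, seq in sequences.items()
        ],
    )


@pytest.fixture
def toy_pair():
    """Two species sharing exactly one 8-mer tryptic peptide."""
    a = make_proteome("A", {"a1": "AAAAAAAKSSSSSSSKCCCCCCCK"})
    b = make_proteome("B", {"b1": "TTTTTTTKSSSSSSSK"})
    return [a, b]
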