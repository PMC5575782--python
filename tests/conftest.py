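import pytest

from ptmhotspots import Alignment, PTMRecord, PTMType, SequenceRecord
from ptmhotspots import datasets


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four rows, ten columns, with gaps and a conserved S column (col 5)."""
    return Alignment(
        [
            SequenceRecord("P1", "MKALSTYQRD", is_query=True),
            SequenceRecord("P2", "MKALSTYQKD", is_query=True),
            SequenceRecord("P3", "MR-LSAYQRD"),
            SequenceRecord("P4", "MKAL-TYWRD"),
        ]
    )


@pytest.fixture
def rgs_demo() -> dict:
    return datasets.rgs_demo()


def phospho(pid: str, pos: int, residue: str = "S", known: bool = False) -> PTMRecord:
    return PTMRecord(pid, pos, residue, PTMType.phosphorylation, known)


def ubiq(pid: str, pos: int) -> PTMRecord:
    return PTMRecord(pid, pos, "K", PTMType.ubiquitination)
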