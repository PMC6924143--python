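import numpy as np
import pytest

from odnscreen import OdnRecord

S1 = "TATGCGTTCGTACTTGATCTGAC"
S2 = "TGCTTTCTTGTCGTGCGGGCTGT"

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def toy_records() -> list[OdnRecord]:
    """Eight short ODNs with activities straddling the 0.4 cutoff."""
    rows = [
        ("a1", "CGTACGTA", 0.62),
        ("a2", "CGGCGGCA", 0.55),
        ("a3", "GGCCGGCC", 0.71),
        ("a4", "ACGTACGT", 0.44),
        ("b1", "TTTATTTA", 0.08),
        ("b2", "TCTATCTA", 0.12),
        ("b3", "ATATATAT", 0.21),
        ("b4", "TTCATTCA", 0.39),
    ]
    return [OdnRecord(id=i, sequence=s, activity=a) for i, s, a in rows]
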