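import numpy as np
import pytest

from cubkit.codons import BACTERIAL_CODE, CodonCountTable


@pytest.fixture(scope="session")
def code():
    return BACTERIAL_CODE


def random_count_table(rng: np.random.Generator, max_count: int = 30,
                       seq_id: str = "rand") -> CodonCountTable:
    """Random counts over the sense codons (stops left at zero)."""
    counts = {
        c: int(rng.integers(0, max_count + 1)) for c in BACTERIAL_CODE.sense_codons
    }
    return CodonCountTable(seq_id=seq_id, counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
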