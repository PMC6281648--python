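import numpy as np
import pytest

from relacs.barcode_design import generate_barcode_set
from relacs.genome_digest import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_genome(rng):
    """A 100 kb single-chromosome random genome at GC 0.5."""
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=100_000)])
    return GenomeSequence({"chr1": seq})


@pytest.fixture(scope="session")
def bc8():
    """8 barcodes, length 8, min pairwise distance >= 3."""
    return generate_barcode_set(8, length=8, min_distance=3, seed=11)


def naive_scan(seq: str, pattern: str = "RGCY", cut_offset: int = 2) -> list[int]:
    """Independent sliding-window oracle for degenerate-motif scanning."""
    codes = {
        "A": "A", "C": "C", "G": "G", "T": "T",
        "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
        "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in codes[p] for j, p in enumerate(pattern)):
            hits.append(i + cut_offset)
    return hits
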