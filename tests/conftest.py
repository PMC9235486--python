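import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracle.py helper


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_matrix():
    """3 reads x 2 CpGs, full coverage: rows MM, MU, UU."""
    return np.array([[1, 1], [1, 0], [0, 0]], dtype=np.int8)


@pytest.fixture
def random_matrices(rng):
    """200 random ternary matrices (<=15 reads x <=10 CpGs, 0-50% missing)."""
    from oracle import random_ternary

    return [random_ternary(rng) for _ in range(200)]


@pytest.fixture
def tiny_fasta(tmp_path):
    """A small two-contig FASTA with known CpG placement, faidx-indexable."""
    rs = np.random.default_rng(7)
    # contig A: 300 bp, CG-rich first window, CG-poor second window
    bases = np.array(list("ACGT"))
    def random_seq(n, rng):
        s = "".join(rng.choice(bases, size=n))
        return s.replace("CG", "CA")  # no accidental CpGs
    win1 = list(random_seq(150, rs))
    for off in (10, 30, 50, 70, 90, 110, 130):  # 7 CpGs
        win1[off:off + 2] = "CG"
    win2 = list(random_seq(150, rs))
    for off in (20, 80):  # 2 CpGs
        win2[off:off + 2] = "CG"
    chrom_a = "".join(win1) + "".join(win2)
    chrom_b = "A" * 200
    path = tmp_path / "ref.fa"
    path.write_text(f">chrA\n{chrom_a}\n>chrB\n{chrom_b}\n")
    return path
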