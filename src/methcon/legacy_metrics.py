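"""Earlier read-level methylation heterogeneity metrics, for comparison.

Reference implementations of the metrics this package is benchmarked
against: methylation entropy, epi-polymorphism, the proportion of
discordant reads (PDR), the methylation haplotype load (MHL), and the
quantitative fraction of discordant read pairs (qFDRP). They share the
ternary region-matrix input of the concordance scorer.

Entropy and epi-polymorphism are epiallele-spectrum statistics: within a
window of k consecutive CpG sites (k = 4, the conventional choice), each
read fully covering the window contributes one of the 2^k binary
epialleles; windows slide across the bin and the per-window values are
averaged. PDR calls a read discordant when it carries both a methylated
and an unmethylated CpG (reads with >= 4 observed CpGs). MHL averages,
with weight proportional to length l, the fraction of fully methylated
runs of l consecutive CpGs. qFDRP is the pooled fraction of discordant
site comparisons over all read pairs — the Hamming-distance complement
of reads concordance, so qFDRP = 1 - RC holds exactly.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .regions import METHYLATED, MISSING, RegionMatrix

DEFAULT_EPIALLELE_K = 4
DEFAULT_PDR_MIN_CPGS = 4


def _values(matrix: RegionMatrix | np.ndarray) -> np.ndarray:
    return matrix.values if isinstance(matrix, RegionMatrix) else np.asarray(matrix)


@dataclass(frozen=True)
class EpialleleTable:
    """Epiallele counts for one window of k consecutive CpG sites."""

    k: int
    counts: dict[tuple[int, ...], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def probabilities(self) -> np.ndarray:
        total = self.total
        return np.array([c / total for c in self.counts.values()])


def epiallele_tables(
    matrix: RegionMatrix | np.ndarray, k: int = DEFAULT_EPIALLELE_K
) -> list[EpialleleTable]:
    """Sliding windows of k consecutive CpG columns, reads fully covering each."""
    values = _values(matrix)
    r, c = values.shape
    tables = []
    for j in range(c - k + 1):
        window = values[:, j : j + k]
        full = ~(window == MISSING).any(axis=1)
        if not full.any():
            continue
        counts = Counter(tuple(int(x) for x in row) for row in window[full])
        tables.append(EpialleleTable(k=k, counts=dict(counts)))
    return tables


def methylation_entropy(table: EpialleleTable) -> float:
    """Shannon entropy of the epiallele spectrum, in bits per CpG site."""
    p = table.probabilities()
    return float(-(p * np.log2(p)).sum() / table.k)


def epipolymorphism(table: EpialleleTable) -> float:
    """1 - sum p_i^2: the probability two random epialleles differ."""
    p = table.probabilities()
    return float(1.0 - (p * p).sum())


def mean_entropy(matrix, k: int = DEFAULT_EPIALLELE_K) -> float:
    tables = epiallele_tables(matrix, k)
    if not tables:
        return float("nan")
    return float(np.mean([methylation_entropy(t) for t in tables]))


def mean_epipolymorphism(matrix, k: int = DEFAULT_EPIALLELE_K) -> float:
    tables = epiallele_tables(matrix, k)
    if not tables:
        return float("nan")
    return float(np.mean([epipolymorphism(t) for t in tables]))


def pdr(matrix, min_cpgs: int = DEFAULT_PDR_MIN_CPGS) -> float:
    """Proportion of discordant reads.

    A read is discordant when it carries at least one methylated and at
    least one unmethylated CpG; only reads with >= min_cpgs observed CpGs
    count. NaN when no read qualifies.
    """
    values = _values(matrix)
    covered = values != MISSING
    eligible = covered.sum(axis=1) >= min_cpgs
    if not eligible.any():
        return float("nan")
    meth_counts = ((values == METHYLATED) & covered).sum(axis=1)[eligible]
    totals = covered.sum(axis=1)[eligible]
    discordant = (meth_counts > 0) & (meth_counts < totals)
    return float(discordant.mean())


def mhl(matrix) -> float:
    """Methylation haplotype load.

    For each run length l = 1..c, f_l is the fraction of fully methylated
    stretches of l consecutive CpGs among all fully covered stretches of
    length l (over all reads); MHL is the l-weighted average
    sum(l * f_l) / sum(l), amplifying long consecutive methylation runs.
    Lengths with no covered stretch are dropped from both sums.
    """
    values = _values(matrix)
    r, c = values.shape
    num = 0.0
    den = 0.0
    for ell in range(1, c + 1):
        total = 0
        fully_meth = 0
        for j in range(c - ell + 1):
            window = values[:, j : j + ell]
            full = ~(window == MISSING).any(axis=1)
            total += int(full.sum())
            fully_meth += int((window[full] == METHYLATED).all(axis=1).sum())
        if total:
            num += ell * (fully_meth / total)
            den += ell
    return float(num / den) if den else float("nan")


def qfdrp(matrix) -> float:
    """Quantitative fraction of discordant read pairs.

    Pooled over all unordered read pairs: (sum of Hamming distances on
    jointly covered sites) / (sum of jointly covered sites). Computed by
    direct pairwise enumeration, independently of the matrix-product
    concordance route; identically equal to 1 - RC.
    """
    values = _values(matrix)
    r = values.shape[0]
    if r < 2:
        return float("nan")
    discordant = 0
    shared = 0
    for i, j in itertools.combinations(range(r), 2):
        a, b = values[i], values[j]
        both = (a != MISSING) & (b != MISSING)
        shared += int(both.sum())
        discordant += int((a[both] != b[both]).sum())
    if shared == 0:
        return float("nan")
    return discordant / shared
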