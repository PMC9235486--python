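"""Concordance scoring of a reads x CpG-sites methylation matrix.

Two paired metrics measure how consistent binary methylation states are
within a genomic bin, along two axes of the matrix:

* **Reads concordance (RC)** — over all pairwise comparisons of reads,
  the fraction of CpG sites covered by both reads at which the two reads
  agree (one minus the normalized Hamming distance, pooled over pairs).
* **CpGs concordance (CC)** — the same quantity over all pairwise
  comparisons of CpG sites (columns), measuring co-methylation of
  neighbouring sites within reads.

Both are computed exactly by matrix products on the binary indicator
matrices M (methylated), N (unmethylated) and T = M + N (covered):
summing the off-diagonal of M·Mᵀ counts, over every ordered pair of
reads, the sites at which both are methylated, and so on. The
off-diagonal sums count each unordered pair twice; the doubled counts
are kept as-is (ratios are unaffected) and the exported integer counts
are therefore the doubled values. The product formulation makes scoring
O(r·c·max(r,c)) and handles coverage above 1000x without subsampling.

Raw concordance is biased by the methylation level (lowest near 0.5), so
each axis is normalized against the concordance expected if states were
drawn independently at the pooled methylation level p of that axis's
comparisons: e = p² + (1 − p)², giving NRC = RC − e_r and NCC = CC − e_c.
Significance is an exact one-sided binomial tail on the concordant-pair
count (lower tail when observed < expected, upper tail otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .regions import METHYLATED, MISSING, UNMETHYLATED, RegionMatrix, mean_methylation

__all__ = [
    "IndicatorMatrices",
    "AxisCounts",
    "ConcordanceScores",
    "build_indicators",
    "reads_axis_counts",
    "cpgs_axis_counts",
    "concordance",
    "binomial_pvalue",
    "score_region",
]

# Smallest p-value reported: exact log tails can drop below the exp()
# underflow threshold at ~1e6 trials; the p-value itself is floored to
# stay in (0, 1] while the exact log tail is reported alongside.
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class IndicatorMatrices:
    """Binary indicator matrices M, N and T = M + N of a region matrix."""

    M: np.ndarray
    N: np.ndarray
    T: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape


@dataclass(frozen=True)
class AxisCounts:
    """Pair counts along one axis (reads or CpG sites).

    All counts come from symmetric off-diagonal sums, so each unordered
    pair of reads (or sites) is counted twice.
    """

    concordant_meth_pairs: int  # both members methylated at a shared site
    concordant_unmeth_pairs: int  # both members unmethylated
    valid_pairs: int  # shared covered sites over all pairs
    pooled_meth: int  # methylated observations pooled over all comparisons
    pooled_unmeth: int


@dataclass(frozen=True)
class ConcordanceScores:
    """Full scoring output for one bin."""

    rc: float
    cc: float
    pr_hat: float  # pooled methylation level, reads axis
    pc_hat: float
    er: float  # expected reads concordance at pr_hat
    ec: float
    nrc: float
    ncc: float
    p_reads: float
    p_cpgs: float
    log_p_reads: float  # natural-log exact tails (no floor)
    log_p_cpgs: float
    reads_axis: AxisCounts
    cpgs_axis: AxisCounts
    n_reads: int
    n_cpgs: int
    mean_meth: float


def build_indicators(matrix: RegionMatrix | np.ndarray) -> IndicatorMatrices:
    values = matrix.values if isinstance(matrix, RegionMatrix) else np.asarray(matrix)
    M = (values == METHYLATED).astype(np.int64)
    N = (values == UNMETHYLATED).astype(np.int64)
    return IndicatorMatrices(M=M, N=N, T=M + N)


def _offdiag_sum(product: np.ndarray) -> int:
    return int(product.sum() - np.trace(product))


def reads_axis_counts(ind: IndicatorMatrices) -> AxisCounts:
    """Pair counts over all pairwise comparisons of reads (rows).

    With fewer than two reads every count is zero and the axis scores
    are undefined downstream.
    """
    M, N, T = ind.M, ind.N, ind.T
    if M.shape[0] < 2:
        return AxisCounts(0, 0, 0, 0, 0)
    return AxisCounts(
        concordant_meth_pairs=_offdiag_sum(M @ M.T),
        concordant_unmeth_pairs=_offdiag_sum(N @ N.T),
        valid_pairs=_offdiag_sum(T @ T.T),
        pooled_meth=_offdiag_sum(T @ M.T),
        pooled_unmeth=_offdiag_sum(T @ N.T),
    )


def cpgs_axis_counts(ind: IndicatorMatrices) -> AxisCounts:
    """Pair counts over all pairwise comparisons of CpG sites (columns)."""
    M, N, T = ind.M, ind.N, ind.T
    if M.shape[1] < 2:
        return AxisCounts(0, 0, 0, 0, 0)
    return AxisCounts(
        concordant_meth_pairs=_offdiag_sum(M.T @ M),
        concordant_unmeth_pairs=_offdiag_sum(N.T @ N),
        valid_pairs=_offdiag_sum(T.T @ T),
        pooled_meth=_offdiag_sum(T.T @ M),
        pooled_unmeth=_offdiag_sum(T.T @ N),
    )


def concordance(counts: AxisCounts) -> tuple[float, float, float, float]:
    """(raw, pooled methylation p, expected concordance e, normalized) for one axis.

    raw = (m + n) / t; p = pooled_meth / (pooled_meth + pooled_unmeth);
    e = p² + (1 − p)²; normalized = raw − e. NaN when t = 0 or the pooled
    total is 0.
    """
    t = counts.valid_pairs
    pooled_total = counts.pooled_meth + counts.pooled_unmeth
    if t == 0 or pooled_total == 0:
        nan = float("nan")
        return nan, nan, nan, nan
    raw = (counts.concordant_meth_pairs + counts.concordant_unmeth_pairs) / t
    p = counts.pooled_meth / pooled_total
    e = p * p + (1.0 - p) * (1.0 - p)
    return raw, p, e, raw - e


def _log_upper_tail(k: int, n: int, p: float) -> float:
    """log P(X >= k) for X ~ Binomial(n, p), stable far beyond underflow.

    Only called when the linear-space tail underflowed, i.e. k is far
    above the mean, where the pmf terms decay geometrically; the series
    is accumulated by running logsumexp until additional terms are
    negligible.
    """
    if k <= 0:
        return 0.0
    log_p, log_q = math.log(p), math.log(1.0 - p)
    lgn = math.lgamma(n + 1)

    def logpmf(i: int) -> float:
        return lgn - math.lgamma(i + 1) - math.lgamma(n - i + 1) + i * log_p + (n - i) * log_q

    total = logpmf(k)
    mean = n * p
    for i in range(k + 1, n + 1):
        term = logpmf(i)
        total = np.logaddexp(total, term)
        if i > mean and term < total - 45.0:
            break
    return float(min(total, 0.0))


def binomial_pvalue(observed: int, trials: int, expected: float) -> tuple[float, float]:
    """Exact one-sided binomial tail for a concordant-pair count.

    Lower tail P(X <= observed) when observed < trials * expected, upper
    tail P(X >= observed) otherwise (the boundary uses the upper tail);
    never doubled. Returns ``(p, log_p)`` where ``log_p`` is the exact
    natural-log tail and ``p = exp(log_p)`` floored to the smallest
    positive normal double so it stays in (0, 1]. Degenerate expectations
    (e <= 0 or e >= 1) give p = 1 by convention; trials = 0 gives NaN.
    """
    if trials == 0:
        return float("nan"), float("nan")
    if not (0.0 < expected < 1.0):
        return 1.0, 0.0
    lower = observed < trials * expected
    if lower:
        p = float(binom.cdf(observed, trials, expected))
    else:
        p = float(binom.sf(observed - 1, trials, expected))
    if p > 0.0:
        log_p = min(math.log(p), 0.0)
    elif lower:
        # P(X <= k) = P(n - X >= n - k) with n - X ~ Binomial(n, 1 - e)
        log_p = _log_upper_tail(trials - observed, trials, 1.0 - expected)
    else:
        log_p = _log_upper_tail(observed, trials, expected)
    p = math.exp(log_p) if log_p > -745.0 else 0.0
    return max(min(p, 1.0), _P_FLOOR), log_p


def score_region(matrix: RegionMatrix | np.ndarray) -> ConcordanceScores:
    """Score one bin: raw and normalized concordance plus exact p-values.

    Deterministic; scales to thousands of reads through the matrix-product
    counts (no subsampling). Degenerate axes (a single read, a single CpG,
    or no valid pairs) yield NaN scores and p-values on that axis.
    """
    ind = build_indicators(matrix)
    ra = reads_axis_counts(ind)
    ca = cpgs_axis_counts(ind)
    rc, pr_hat, er, nrc = concordance(ra)
    cc, pc_hat, ec, ncc = concordance(ca)
    if math.isnan(rc):
        p_reads = log_p_reads = float("nan")
    else:
        p_reads, log_p_reads = binomial_pvalue(
            ra.concordant_meth_pairs + ra.concordant_unmeth_pairs, ra.valid_pairs, er
        )
    if math.isnan(cc):
        p_cpgs = log_p_cpgs = float("nan")
    else:
        p_cpgs, log_p_cpgs = binomial_pvalue(
            ca.concordant_meth_pairs + ca.concordant_unmeth_pairs, ca.valid_pairs, ec
        )
    values = matrix.values if isinstance(matrix, RegionMatrix) else np.asarray(matrix)
    return ConcordanceScores(
        rc=rc,
        cc=cc,
        pr_hat=pr_hat,
        pc_hat=pc_hat,
        er=er,
        ec=ec,
        nrc=nrc,
        ncc=ncc,
        p_reads=p_reads,
        p_cpgs=p_cpgs,
        log_p_reads=log_p_reads,
        log_p_cpgs=log_p_cpgs,
        reads_axis=ra,
        cpgs_axis=ca,
        n_reads=values.shape[0],
        n_cpgs=values.shape[1],
        mean_meth=mean_methylation(values),
    )
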