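"""Genomic bins, reads x CpG-site matrices, and bin-level filters.

The genome is tiled into fixed-width windows (150 bp by default, matching
typical short-read lengths). For each window the CpG sites (forward-strand
``CG`` dinucleotides) are enumerated from the reference, and the fragments
overlapping the window are assembled into a ternary reads x CpG-sites
matrix: methylated, unmethylated or missing. All downstream concordance
scoring operates on these matrices.

Coordinate conventions, used everywhere in this package:

* CpG identity is the 1-based position of the C on the forward strand
  (calls on the reverse strand at the G are shifted by -1 to the C).
* Genomic intervals (bins, region queries) are half-open ``[start, end)``
  in 0-based coordinates; a CpG with 1-based position ``p`` lies in the
  interval iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .records import MethFragment

# Ternary cell encoding of a RegionMatrix.
METHYLATED: int = 1
UNMETHYLATED: int = 0
MISSING: int = -1

DEFAULT_BIN_WIDTH = 150
DEFAULT_MIN_CPGS = 6
DEFAULT_MIN_READS = 6
DEFAULT_METH_LOW = 0.05
DEFAULT_METH_HIGH = 0.95


@dataclass(frozen=True)
class GenomicBin:
    """A genomic window with its CpG sites.

    ``start``/``end`` are 0-based half-open; ``cpg_positions`` are the
    1-based forward-strand C positions of the CpGs inside the window,
    strictly increasing.
    """

    chromosome: str
    start: int
    end: int
    cpg_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        pos = self.cpg_positions
        if any(pos[i] >= pos[i + 1] for i in range(len(pos) - 1)):
            raise ValueError("cpg_positions must be strictly increasing")
        if pos and not (self.start <= pos[0] - 1 and pos[-1] - 1 < self.end):
            raise ValueError("cpg_positions outside [start, end)")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class RegionMatrix:
    """Ternary reads x CpG-sites matrix for one genomic bin.

    ``values`` is an ``(r, c)`` int8 array with cells METHYLATED (1),
    UNMETHYLATED (0) or MISSING (-1); row ``i`` is fragment
    ``row_ids[i]``, column ``j`` is CpG ``bin.cpg_positions[j]``.
    """

    bin: GenomicBin
    row_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        r, c = self.values.shape
        if r != len(self.row_ids):
            raise ValueError("row_ids length does not match matrix rows")
        if c != self.bin.n_cpgs:
            raise ValueError("matrix columns do not match bin CpG count")
        bad = ~np.isin(self.values, (METHYLATED, UNMETHYLATED, MISSING))
        if bad.any():
            raise ValueError("cells must be 1 (meth), 0 (unmeth) or -1 (missing)")

    @property
    def n_reads(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]


def _iter_cg_positions(sequence: str) -> Iterator[int]:
    """Yield 0-based indices of the C of each forward-strand CG (case-insensitive)."""
    seq = sequence.upper()
    i = seq.find("CG")
    while i != -1:
        yield i
        i = seq.find("CG", i + 1)


def enumerate_bins(
    reference_fasta,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    chromosomes: Sequence[str] | None = None,
) -> Iterator[GenomicBin]:
    """Tile each chromosome into non-overlapping windows and keep CpG-rich ones.

    Parameters
    ----------
    reference_fasta
        Path to an (indexable) FASTA file, or an already-open
        :class:`pyfaidx.Fasta`.
    bin_width
        Window width in bp; windows restart at each chromosome origin and
        the last partial window is kept if it passes the CpG filter.
    min_cpgs
        Minimum number of CpG sites for a window to be emitted.
    chromosomes
        Restrict to these sequence names; a name absent from the FASTA is
        an error.
    """
    import pyfaidx

    fasta = (
        reference_fasta
        if isinstance(reference_fasta, pyfaidx.Fasta)
        else pyfaidx.Fasta(str(reference_fasta))
    )
    names = list(chromosomes) if chromosomes is not None else list(fasta.keys())
    for name in names:
        if name not in fasta:
            raise KeyError(f"chromosome {name!r} not present in FASTA")
        seq = str(fasta[name][:])
        length = len(seq)
        # bucket CpG C-positions by window
        per_bin: dict[int, list[int]] = {}
        for i in _iter_cg_positions(seq):
            per_bin.setdefault(i // bin_width, []).append(i + 1)  # 1-based C
        n_bins = (length + bin_width - 1) // bin_width
        for b in range(n_bins):
            cpgs = per_bin.get(b, ())
            if len(cpgs) >= min_cpgs:
                yield GenomicBin(
                    chromosome=name,
                    start=b * bin_width,
                    end=min((b + 1) * bin_width, length),
                    cpg_positions=tuple(cpgs),
                )


def bins_from_bed(bed_path, reference_fasta, min_cpgs: int = 0) -> Iterator[GenomicBin]:
    """Build bins from user-supplied BED intervals instead of genome tiling.

    BED is 0-based half-open; CpGs are enumerated from the reference within
    each interval. Intervals with fewer than ``min_cpgs`` CpGs are dropped.
    """
    import pyfaidx

    fasta = (
        reference_fasta
        if isinstance(reference_fasta, pyfaidx.Fasta)
        else pyfaidx.Fasta(str(reference_fasta))
    )
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if chrom not in fasta:
                raise KeyError(f"chromosome {chrom!r} not present in FASTA")
            # include one extra base so a CG whose C is the interval's last base counts
            seq = str(fasta[chrom][start : end + 1])
            cpgs = tuple(
                start + i + 1 for i in _iter_cg_positions(seq) if start + i < end
            )
            if len(cpgs) >= min_cpgs:
                yield GenomicBin(chromosome=chrom, start=start, end=end, cpg_positions=cpgs)


def build_region_matrix(fragments: Iterable[MethFragment], bin: GenomicBin) -> RegionMatrix:
    """Assemble the ternary reads x CpG matrix for one bin.

    Each fragment with at least one observation at a bin CpG becomes a row;
    bin CpGs the fragment does not observe are missing. Fragments on other
    chromosomes or without bin-CpG observations are ignored.
    """
    col_of = {p: j for j, p in enumerate(bin.cpg_positions)}
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for frag in fragments:
        if frag.chromosome != bin.chromosome:
            continue
        row = np.full(len(col_of), MISSING, dtype=np.int8)
        hit = False
        for pos, state in frag.observations:
            j = col_of.get(pos)
            if j is not None:
                row[j] = METHYLATED if state else UNMETHYLATED
                hit = True
        if hit:
            rows.append(row)
            ids.append(frag.fragment_id)
    values = (
        np.vstack(rows) if rows else np.empty((0, len(col_of)), dtype=np.int8)
    )
    return RegionMatrix(bin=bin, row_ids=ids, values=values)


def mean_methylation(matrix: RegionMatrix | np.ndarray) -> float:
    """Fraction of methylated cells among non-missing cells; NaN if none."""
    values = matrix.values if isinstance(matrix, RegionMatrix) else np.asarray(matrix)
    covered = values != MISSING
    n = int(covered.sum())
    if n == 0:
        return float("nan")
    return float((values == METHYLATED).sum() / n)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.passed


def bin_filters(
    matrix: RegionMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    meth_low: float | None = DEFAULT_METH_LOW,
    meth_high: float | None = DEFAULT_METH_HIGH,
) -> FilterResult:
    """Bin-level QC: enough reads, enough CpGs, intermediate methylation.

    The intermediate-methylation window (``meth_low < mean < meth_high``)
    is skipped when either cutoff is None, so the same matrices can be
    re-screened with different methylation cutoffs (e.g. the CpG-island
    hypermethylation stage).
    """
    if matrix.n_reads < min_reads:
        return FilterResult(False, f"reads {matrix.n_reads} < {min_reads}")
    if matrix.n_cpgs < min_cpgs:
        return FilterResult(False, f"cpgs {matrix.n_cpgs} < {min_cpgs}")
    if meth_low is not None and meth_high is not None:
        m = mean_methylation(matrix)
        if not (meth_low < m < meth_high):
            return FilterResult(False, f"mean methylation {m:.3f} not intermediate")
    return FilterResult(True)
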