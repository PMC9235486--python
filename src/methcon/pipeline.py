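"""Tabular end-to-end scoring: recordings + bins -> per-bin score table."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .concord import score_region
from .legacy_metrics import mean_entropy, mean_epipolymorphism, mhl, pdr, qfdrp
from .patterns import Thresholds, classify_bin
from .records import MethFragment, read_records
from .regions import (
    DEFAULT_METH_HIGH,
    DEFAULT_METH_LOW,
    DEFAULT_MIN_CPGS,
    DEFAULT_MIN_READS,
    GenomicBin,
    RegionMatrix,
    bin_filters,
    build_region_matrix,
)

SCORE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_reads",
    "n_cpgs",
    "mean_meth",
    "RC",
    "CC",
    "NRC",
    "NCC",
    "Pr",
    "Pc",
]
COUNT_COLUMNS = ["mr", "nr", "tr", "mpr", "npr", "mc", "nc", "tc", "mpc", "npc"]
LEGACY_COLUMNS = ["entropy", "epipolymorphism", "PDR", "MHL", "qFDRP"]


def score_matrices(
    matrices: Iterable[RegionMatrix],
    min_reads: int = DEFAULT_MIN_READS,
    min_cpgs: int = DEFAULT_MIN_CPGS,
    meth_low: float | None = DEFAULT_METH_LOW,
    meth_high: float | None = DEFAULT_METH_HIGH,
    with_counts: bool = False,
    with_legacy_metrics: bool = False,
    keep_filtered: bool = False,
) -> pd.DataFrame:
    """Score a stream of region matrices into a tidy per-bin table.

    Bins failing the read/CpG/intermediate-methylation filters are
    dropped unless ``keep_filtered``, in which case they appear with a
    ``filter_reason`` column instead of scores.
    """
    rows = []
    for matrix in matrices:
        b = matrix.bin
        verdict = bin_filters(
            matrix,
            min_reads=min_reads,
            min_cpgs=min_cpgs,
            meth_low=meth_low,
            meth_high=meth_high,
        )
        row: dict = {"chrom": b.chromosome, "start": b.start, "end": b.end}
        if not verdict:
            if keep_filtered:
                row.update(
                    n_reads=matrix.n_reads,
                    n_cpgs=matrix.n_cpgs,
                    filter_reason=verdict.reason,
                )
                rows.append(row)
            continue
        s = score_region(matrix)
        row.update(
            n_reads=s.n_reads,
            n_cpgs=s.n_cpgs,
            mean_meth=s.mean_meth,
            RC=s.rc,
            CC=s.cc,
            NRC=s.nrc,
            NCC=s.ncc,
            Pr=s.p_reads,
            Pc=s.p_cpgs,
        )
        if keep_filtered:
            row["filter_reason"] = ""
        if with_counts:
            ra, ca = s.reads_axis, s.cpgs_axis
            row.update(
                mr=ra.concordant_meth_pairs,
                nr=ra.concordant_unmeth_pairs,
                tr=ra.valid_pairs,
                mpr=ra.pooled_meth,
                npr=ra.pooled_unmeth,
                mc=ca.concordant_meth_pairs,
                nc=ca.concordant_unmeth_pairs,
                tc=ca.valid_pairs,
                mpc=ca.pooled_meth,
                npc=ca.pooled_unmeth,
            )
        if with_legacy_metrics:
            row.update(
                entropy=mean_entropy(matrix),
                epipolymorphism=mean_epipolymorphism(matrix),
                PDR=pdr(matrix),
                MHL=mhl(matrix),
                qFDRP=qfdrp(matrix),
            )
        rows.append(row)
    columns = SCORE_COLUMNS.copy()
    if keep_filtered:
        columns += ["filter_reason"]
    if with_counts:
        columns += COUNT_COLUMNS
    if with_legacy_metrics:
        columns += LEGACY_COLUMNS
    return pd.DataFrame(rows, columns=columns)


def matrices_from_records(
    records_path, bins: Iterable[GenomicBin]
) -> Iterable[RegionMatrix]:
    """Build one region matrix per bin from a recording file.

    Recordings are loaded once and indexed by chromosome; suitable for
    the file sizes this tool targets (per-region studies, test genomes).
    """
    by_chrom: dict[str, list[MethFragment]] = {}
    for frag in read_records(records_path):
        by_chrom.setdefault(frag.chromosome, []).append(frag)
    for b in bins:
        frags = [
            f for f in by_chrom.get(b.chromosome, []) if f.overlaps(b.start, b.end)
        ]
        yield build_region_matrix(frags, b)


def score_records(records_path, bins: Iterable[GenomicBin], **kwargs) -> pd.DataFrame:
    """Score every bin against a recording file (see score_matrices)."""
    return score_matrices(matrices_from_records(records_path, bins), **kwargs)


def classify_table(
    scores: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Append a pattern ``label`` column to a score table."""
    from types import SimpleNamespace

    th = thresholds or Thresholds()
    labels = []
    for _, row in scores.iterrows():
        shim = SimpleNamespace(
            nrc=row["NRC"], ncc=row["NCC"], p_reads=row["Pr"], p_cpgs=row["Pc"]
        )
        labels.append(classify_bin(shim, th).label)
    out = scores.copy()
    out["label"] = labels
    return out
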