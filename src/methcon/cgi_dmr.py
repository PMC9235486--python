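"""Case-control screening of CpG-island bins for hypermethylation.

Workflow: CpG islands are intersected with the genome's 150-bp tiling;
for each clipped bin a mean methylation level is computed per sample.
Bins that are stably lowly methylated across the control samples
(mean < 0.20, sample SD < 0.05) are screened, and a bin is called
hypermethylated in a case sample — independently per case — when that
sample's methylation exceeds the control mean by more than 0.1. The
methylation-pattern composition of the called bins then summarizes *how*
the gained methylation is organized (uniform gains suggest a clonal or
cell-population event; disordered gains suggest stochastic erosion).

The bin-by-sample methylation table is a pandas DataFrame (rows = bin
ids, columns = sample names, values in [0, 1] or NaN) plus a mapping of
sample name to group ("control" / "case").
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import DEFAULT_BIN_WIDTH, DEFAULT_MIN_CPGS, GenomicBin

DEFAULT_CONTROL_MEAN_CUT = 0.20
DEFAULT_CONTROL_SD_CUT = 0.05
DEFAULT_HYPER_DELTA = 0.10


def bin_id(bin: GenomicBin) -> str:
    return f"{bin.chromosome}:{bin.start}-{bin.end}"


def cgi_bins(
    cgi_bed,
    reference_fasta,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_cpgs: int = DEFAULT_MIN_CPGS,
) -> Iterator[GenomicBin]:
    """Intersect CpG-island intervals with the genome tiling.

    Tiling windows are aligned to the chromosome origin; each window
    overlapping an island is clipped to the island boundaries and kept
    if the clipped piece still holds >= min_cpgs CpGs.
    """
    import pyfaidx

    fasta = (
        reference_fasta
        if isinstance(reference_fasta, pyfaidx.Fasta)
        else pyfaidx.Fasta(str(reference_fasta))
    )
    from .regions import _iter_cg_positions

    with open(cgi_bed) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start_s, end_s = line.split("\t")[:3]
            start, end = int(start_s), int(end_s)
            if chrom not in fasta:
                raise KeyError(f"chromosome {chrom!r} not present in FASTA")
            first = (start // bin_width) * bin_width
            for b0 in range(first, end, bin_width):
                lo, hi = max(b0, start), min(b0 + bin_width, end)
                if hi <= lo:
                    continue
                seq = str(fasta[chrom][lo : hi + 1])
                cpgs = tuple(
                    lo + i + 1 for i in _iter_cg_positions(seq) if lo + i < hi
                )
                if len(cpgs) >= min_cpgs:
                    yield GenomicBin(
                        chromosome=chrom, start=lo, end=hi, cpg_positions=cpgs
                    )


def _split_groups(groups: Mapping[str, str]) -> tuple[list[str], list[str]]:
    controls = [s for s, g in groups.items() if g == "control"]
    cases = [s for s, g in groups.items() if g == "case"]
    if not controls or not cases:
        raise ValueError("need at least one control and one case sample")
    return controls, cases


def select_control_stable_bins(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    mean_cut: float = DEFAULT_CONTROL_MEAN_CUT,
    sd_cut: float = DEFAULT_CONTROL_SD_CUT,
) -> pd.Index:
    """Bins stably lowly methylated in controls.

    Selected iff control mean < mean_cut and control sample SD (n-1
    denominator) < sd_cut, with every control defined (any NaN rejects
    the bin).
    """
    controls, _ = _split_groups(groups)
    ctrl = table[controls]
    complete = ctrl.notna().all(axis=1)
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    keep = complete & (mean < mean_cut) & (sd < sd_cut)
    return table.index[keep]


def call_hyper_bins(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    selected: Sequence[str] | pd.Index,
    delta: float = DEFAULT_HYPER_DELTA,
) -> dict[str, pd.Index]:
    """Per case sample, bins whose methylation gain over controls exceeds delta.

    Called iff case - control_mean > delta (strict); bins where the case
    sample is NaN are not evaluable for that sample.
    """
    controls, cases = _split_groups(groups)
    sub = table.loc[pd.Index(selected)]
    ctrl_mean = sub[controls].mean(axis=1)
    out: dict[str, pd.Index] = {}
    for case in cases:
        vals = sub[case]
        called = vals.notna() & ((vals - ctrl_mean) > delta)
        out[case] = sub.index[called]
    return out


def pattern_composition_of_dmrs(
    calls: Mapping[str, Mapping[str, str]] | Mapping[str, str],
    hyper_bins: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Pattern composition of each case sample's hypermethylated bins.

    ``calls`` maps bin id -> pattern label, either one mapping shared by
    all samples or one mapping per case sample. Returns a DataFrame
    (rows = case samples) with the fraction of identical / uniform /
    disordered among the classified hyper bins, plus counts.
    """
    from .patterns import composition

    per_sample = isinstance(next(iter(calls.values()), None), Mapping)
    rows = {}
    for case, bins in hyper_bins.items():
        lookup = calls[case] if per_sample else calls
        labels = [lookup[b] for b in bins if b in lookup]
        comp = composition(labels)
        rows[case] = {
            "identical": comp["identical"],
            "uniform": comp["uniform"],
            "disordered": comp["disordered"],
            "n_hyper_bins": len(bins),
            "n_classified": sum(
                1 for l in labels if l in ("identical", "uniform", "disordered")
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
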