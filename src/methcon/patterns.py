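"""Classification of scored bins into canonical methylation patterns.

Intermediately methylated bins fall into three canonical read-level
patterns:

* **identical** — reads agree with each other but adjacent CpG sites
  within a read differ (e.g. a fixed, interspersed methylation footprint
  shared by all molecules): high NRC, low NCC.
* **uniform** — CpG sites within each read agree but reads split into
  divergent groups (allele-specific methylation, cell-type mixtures):
  high NCC, low NRC.
* **disordered** — low concordance on both axes (stochastic erosion).

The decision rules threshold the normalized concordance scores and their
binomial p-values; a bin in the high-NRC/high-NCC corner or otherwise
between the rules is *ambiguous*, and a bin with undefined scores is
*insufficient*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .concord import ConcordanceScores

LABELS = ("identical", "uniform", "disordered", "ambiguous", "insufficient")


@dataclass(frozen=True)
class Thresholds:
    """Classification cutoffs.

    ncc_cut / nrc_cut
        The high-vs-low boundary for the normalized scores (strict on
        both sides; default 0.1).
    p_low
        Significance required of the concordant axis (default 1e-10).
    p_high
        Insignificance required of both axes for "disordered"
        (default 1e-5).
    """

    ncc_cut: float = 0.1
    nrc_cut: float = 0.1
    p_low: float = 1e-10
    p_high: float = 1e-5


@dataclass(frozen=True)
class PatternCall:
    label: str
    thresholds_used: Thresholds
    nrc: float
    ncc: float
    p_reads: float
    p_cpgs: float


def classify_bin(
    scores: ConcordanceScores, thresholds: Thresholds | None = None
) -> PatternCall:
    """Assign one scored bin a pattern label.

    uniform:    NCC > ncc_cut, NRC < nrc_cut, Pc < p_low
    identical:  NRC > nrc_cut, NCC < ncc_cut, Pr < p_low
    disordered: NCC < ncc_cut, NRC < nrc_cut, Pr > p_high and Pc > p_high
    otherwise ambiguous; any undefined score -> insufficient.

    The disordered rule requires *both* p-values to be unremarkable; the
    significant p-value for uniform/identical is the one belonging to the
    concordant axis. All cutoffs are strict inequalities, which makes the
    three rules mutually exclusive.
    """
    th = thresholds or Thresholds()
    nrc, ncc, pr, pc = scores.nrc, scores.ncc, scores.p_reads, scores.p_cpgs
    if any(map(math.isnan, (nrc, ncc, pr, pc))):
        label = "insufficient"
    elif ncc > th.ncc_cut and nrc < th.nrc_cut and pc < th.p_low:
        label = "uniform"
    elif nrc > th.nrc_cut and ncc < th.ncc_cut and pr < th.p_low:
        label = "identical"
    elif ncc < th.ncc_cut and nrc < th.nrc_cut and pr > th.p_high and pc > th.p_high:
        label = "disordered"
    else:
        label = "ambiguous"
    return PatternCall(
        label=label, thresholds_used=th, nrc=nrc, ncc=ncc, p_reads=pr, p_cpgs=pc
    )


def composition(
    calls: Iterable[PatternCall | str], include_unclassified: bool = False
) -> Mapping[str, float]:
    """Fraction of each pattern among a set of calls.

    By default fractions are over the three canonical labels only
    (ambiguous/insufficient excluded from the denominator but reported
    under their own keys as fractions of all calls); with
    ``include_unclassified`` every label shares one denominator. Empty
    input gives NaN fractions.
    """
    labels = [c.label if isinstance(c, PatternCall) else c for c in calls]
    total = len(labels)
    counts = {lab: labels.count(lab) for lab in LABELS}
    out: dict[str, float] = {}
    if include_unclassified:
        denom = total
        for lab in LABELS:
            out[lab] = counts[lab] / denom if denom else float("nan")
    else:
        denom = counts["identical"] + counts["uniform"] + counts["disordered"]
        for lab in ("identical", "uniform", "disordered"):
            out[lab] = counts[lab] / denom if denom else float("nan")
        for lab in ("ambiguous", "insufficient"):
            out[lab] = counts[lab] / total if total else float("nan")
    return out
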