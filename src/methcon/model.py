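"""Model/results interface over the concordance scorer.

``MethylationConcordance`` wraps one region matrix the way a statistical
model wraps its data: construct it from a matrix (or from recordings and
a bin), call :meth:`~MethylationConcordance.fit`, and read the estimates,
their significance and a ``summary()`` table off the returned
:class:`ConcordanceResults`. Pattern classification, the legacy
heterogeneity metrics and the lollipop plot hang off the results object.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from . import legacy_metrics
from .concord import ConcordanceScores, score_region
from .patterns import PatternCall, Thresholds, classify_bin
from .records import MethFragment
from .regions import GenomicBin, RegionMatrix, build_region_matrix


class MethylationConcordance:
    """Read-level methylation concordance model for one genomic bin.

    Parameters
    ----------
    matrix
        The ternary reads x CpG-sites matrix to score, either a
        :class:`RegionMatrix` or a bare array (1 = methylated,
        0 = unmethylated, -1 = missing).

    Examples
    --------
    >>> from methcon import MethylationConcordance, simulate
    >>> m = simulate.simulate_pattern(simulate.SimulationSpec("P5", seed=1))
    >>> res = MethylationConcordance(m).fit()
    >>> res.ncc > res.nrc
    True
    """

    def __init__(self, matrix: RegionMatrix | np.ndarray):
        if not isinstance(matrix, RegionMatrix):
            from .simulate import synthetic_bin

            values = np.asarray(matrix, dtype=np.int8)
            matrix = RegionMatrix(
                bin=synthetic_bin(values.shape[1]),
                row_ids=[f"read{i}" for i in range(values.shape[0])],
                values=values,
            )
        self.matrix = matrix

    @classmethod
    def from_fragments(
        cls, fragments: Iterable[MethFragment], bin: GenomicBin
    ) -> "MethylationConcordance":
        return cls(build_region_matrix(fragments, bin))

    @classmethod
    def from_records(cls, path, bin: GenomicBin) -> "MethylationConcordance":
        from .records import read_records

        region = (bin.chromosome, bin.start, bin.end)
        return cls.from_fragments(read_records(path, region=region), bin)

    def fit(self) -> "ConcordanceResults":
        """Compute the concordance scores and exact binomial p-values."""
        return ConcordanceResults(self, score_region(self.matrix))


class ConcordanceResults:
    """Fitted concordance scores for one bin.

    Exposes the raw scores (``rc``, ``cc``), the pooled methylation
    levels and expected concordances (``pr_hat``/``er``, ``pc_hat``/
    ``ec``), the normalized scores (``nrc``, ``ncc``) and exact binomial
    p-values (``p_reads``, ``p_cpgs``), plus classification, legacy
    metrics and plotting.
    """

    def __init__(self, model: MethylationConcordance, scores: ConcordanceScores):
        self.model = model
        self.scores = scores

    def __getattr__(self, name: str):
        try:
            return getattr(self.scores, name)
        except AttributeError:
            raise AttributeError(name) from None

    def classify(self, thresholds: Thresholds | None = None) -> PatternCall:
        """Label the bin identical / uniform / disordered (or ambiguous)."""
        return classify_bin(self.scores, thresholds)

    def legacy_metrics(self) -> dict[str, float]:
        """Entropy, epi-polymorphism, PDR, MHL and qFDRP on the same matrix."""
        m = self.model.matrix
        return {
            "entropy": legacy_metrics.mean_entropy(m),
            "epipolymorphism": legacy_metrics.mean_epipolymorphism(m),
            "pdr": legacy_metrics.pdr(m),
            "mhl": legacy_metrics.mhl(m),
            "qfdrp": legacy_metrics.qfdrp(m),
        }

    def plot(self, **kwargs):
        """Lollipop plot of the underlying matrix (see viz.plot_lollipop)."""
        from .viz import plot_lollipop

        return plot_lollipop(self.model.matrix, **kwargs)

    def summary(self) -> str:
        s = self.scores
        b = self.model.matrix.bin
        call = self.classify()
        lines = [
            "Methylation concordance",
            "=" * 55,
            f"region           {b.chromosome}:{b.start}-{b.end}",
            f"reads / CpGs     {s.n_reads} / {s.n_cpgs}",
            f"mean methylation {s.mean_meth:.4f}",
            "-" * 55,
            f"{'':18}{'reads axis':>14}{'CpGs axis':>14}",
            f"{'raw concordance':18}{s.rc:>14.4f}{s.cc:>14.4f}",
            f"{'pooled meth p':18}{s.pr_hat:>14.4f}{s.pc_hat:>14.4f}",
            f"{'expected':18}{s.er:>14.4f}{s.ec:>14.4f}",
            f"{'normalized':18}{s.nrc:>14.4f}{s.ncc:>14.4f}",
            f"{'P-value':18}{s.p_reads:>14.3e}{s.p_cpgs:>14.3e}",
            "-" * 55,
            f"pattern          {call.label}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        s = self.scores
        return (
            f"<ConcordanceResults NRC={s.nrc:.3f} NCC={s.ncc:.3f} "
            f"Pr={s.p_reads:.2e} Pc={s.p_cpgs:.2e}>"
        )
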