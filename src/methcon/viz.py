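"""Lollipop plots of read-level methylation matrices.

One horizontal line per read, one marker per observed CpG: filled circle
= methylated, open circle = unmethylated, no marker where the read did
not cover the site.
"""

from __future__ import annotations

import numpy as np

from .regions import METHYLATED, MISSING, RegionMatrix


def _read_order(values: np.ndarray) -> np.ndarray:
    """Deterministic row order: first covered CpG, then methylation count."""
    covered = values != MISSING
    first = np.where(covered.any(axis=1), covered.argmax(axis=1), values.shape[1])
    meth = (values == METHYLATED).sum(axis=1)
    return np.lexsort((np.arange(values.shape[0]), -meth, first))


def plot_lollipop(
    matrix: RegionMatrix,
    path=None,
    ax=None,
    sort_reads: bool = True,
    spacing: str = "genomic",
    marker_size: float = 60.0,
):
    """Render a region matrix as a lollipop plot.

    Parameters
    ----------
    matrix
        The region matrix to draw; must contain at least one read.
    path
        If given, the figure is written there (format from the extension;
        PDF and SVG stay vector graphics).
    ax
        Existing matplotlib axes to draw into.
    sort_reads
        Sort reads by first covered CpG then methylation count for a
        reproducible layout; otherwise keep matrix order.
    spacing
        'genomic' places CpGs at their genomic coordinates, 'uniform'
        spaces them evenly.

    Returns the matplotlib Axes.
    """
    import matplotlib

    if path is not None and matplotlib.get_backend().lower() != "agg":
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = matrix.values
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("cannot plot an empty region matrix")
    if spacing not in ("genomic", "uniform"):
        raise ValueError("spacing must be 'genomic' or 'uniform'")

    if ax is None:
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.5 * values.shape[1]), max(2.0, 0.3 * values.shape[0]))
        )
    else:
        fig = ax.figure

    xs = (
        np.asarray(matrix.bin.cpg_positions, dtype=float)
        if spacing == "genomic"
        else np.arange(values.shape[1], dtype=float)
    )
    order = _read_order(values) if sort_reads else np.arange(values.shape[0])
    for row_idx, i in enumerate(order):
        row = values[i]
        covered = row != MISSING
        y = row_idx
        if covered.any():
            ax.plot(
                [xs[covered].min(), xs[covered].max()],
                [y, y],
                color="0.6",
                lw=0.8,
                zorder=1,
            )
        meth = row == METHYLATED
        ax.scatter(
            xs[covered & meth],
            np.full(int((covered & meth).sum()), y),
            s=marker_size,
            facecolors="black",
            edgecolors="black",
            zorder=2,
        )
        unmeth = covered & ~meth
        ax.scatter(
            xs[unmeth],
            np.full(int(unmeth.sum()), y),
            s=marker_size,
            facecolors="white",
            edgecolors="black",
            zorder=2,
        )
    ax.set_yticks([])
    ax.set_xlabel(
        f"{matrix.bin.chromosome}:{matrix.bin.start}-{matrix.bin.end}"
        if spacing == "genomic"
        else "CpG site"
    )
    ax.set_ylim(-0.8, len(order) - 0.2)
    ax.invert_yaxis()
    if path is not None:
        fig.savefig(str(path), bbox_inches="tight")
        plt.close(fig)
    return ax
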