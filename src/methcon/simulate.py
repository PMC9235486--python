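"""Synthetic region matrices for the canonical methylation patterns.

The simulator generates the benchmark conditions used throughout the test
suite: five pattern archetypes at 12 reads x 8 CpG sites with a target
methylation level around 0.25, optionally corrupted by random state flips
("methylation mutations", 5% by default) to mimic real bisulfite data.

Pattern semantics (P1/P3/P5 are the canonical patterns; P2/P4 are
half-way mixtures kept only to fill the five-pattern API):

* P1 *identical* — every read carries the same fixed footprint:
  ``round(target_meth * c)`` methylated columns, evenly interspersed.
* P2 — column-wise 50/50 mixture of P1 and P3.
* P3 *disordered* — iid Bernoulli(target_meth) cells.
* P4 — row-wise 50/50 mixture of P3 and P5.
* P5 *uniform* — each read fully methylated with probability
  target_meth, else fully unmethylated.

All generators are deterministic given the seed. Matrices are complete
(no missing cells); ``simulate_null`` adds iid missingness for
calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import MethFragment
from .regions import (
    METHYLATED,
    MISSING,
    UNMETHYLATED,
    GenomicBin,
    RegionMatrix,
)

PATTERNS = ("P1", "P2", "P3", "P4", "P5")


@dataclass(frozen=True)
class SimulationSpec:
    pattern: str
    n_reads: int = 12
    n_cpgs: int = 8
    target_meth: float = 0.25
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.n_reads < 2 or self.n_cpgs < 2:
            raise ValueError("need at least 2 reads and 2 CpG sites")
        if not 0.0 <= self.target_meth <= 1.0:
            raise ValueError("target_meth must be in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")


def synthetic_bin(n_cpgs: int, chromosome: str = "sim", start: int = 0) -> GenomicBin:
    """A synthetic bin with evenly spaced CpGs, for simulator output."""
    width = max(150, 2 * n_cpgs)
    step = width // (n_cpgs + 1)
    positions = tuple(start + (j + 1) * step + 1 for j in range(n_cpgs))
    return GenomicBin(
        chromosome=chromosome, start=start, end=start + width, cpg_positions=positions
    )


def _identical_columns(n_cpgs: int, target_meth: float) -> np.ndarray:
    """The fixed column-state vector of P1: k methylated columns, interspersed."""
    k = int(round(target_meth * n_cpgs))
    cols = np.full(n_cpgs, UNMETHYLATED, dtype=np.int8)
    if k > 0:
        idx = np.linspace(0, n_cpgs - 1, num=k + 2)[1:-1]
        chosen = sorted(set(int(round(x)) for x in idx))
        while len(chosen) < k:  # rounding collisions at small c
            chosen.append(next(j for j in range(n_cpgs) if j not in chosen))
        cols[sorted(chosen)[:k] if len(chosen) > k else chosen] = METHYLATED
    return cols


def _base_matrix(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    r, c, p = spec.n_reads, spec.n_cpgs, spec.target_meth
    if spec.pattern == "P1":
        return np.tile(_identical_columns(c, p), (r, 1))
    if spec.pattern == "P3":
        return (rng.random((r, c)) < p).astype(np.int8)
    if spec.pattern == "P5":
        rows = (rng.random(r) < p).astype(np.int8)
        return np.repeat(rows[:, None], c, axis=1)
    if spec.pattern == "P2":  # column-wise mixture of P1 and P3
        out = np.tile(_identical_columns(c, p), (r, 1))
        mix = rng.permutation(c)[: c // 2]
        out[:, mix] = (rng.random((r, len(mix))) < p).astype(np.int8)
        return out
    # P4: row-wise mixture of P3 and P5
    out = (rng.random((r, c)) < p).astype(np.int8)
    mix = rng.permutation(r)[: r // 2]
    rows = (rng.random(len(mix)) < p).astype(np.int8)
    out[mix, :] = np.repeat(rows[:, None], c, axis=1)
    return out


def simulate_pattern(spec: SimulationSpec) -> RegionMatrix:
    """Generate one complete pattern matrix (noise applied per the spec)."""
    rng = np.random.default_rng(spec.seed)
    values = _base_matrix(spec, rng)
    matrix = RegionMatrix(
        bin=synthetic_bin(spec.n_cpgs),
        row_ids=[f"read{i}" for i in range(spec.n_reads)],
        values=values,
    )
    if spec.noise_rate > 0:
        matrix = add_noise(matrix, spec.noise_rate, rng=rng)
    return matrix


def add_noise(
    matrix: RegionMatrix,
    noise_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegionMatrix:
    """Flip each non-missing cell independently with probability noise_rate."""
    if rng is None:
        rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    flip = (rng.random(values.shape) < noise_rate) & (values != MISSING)
    values[flip] = 1 - values[flip]
    return RegionMatrix(bin=matrix.bin, row_ids=list(matrix.row_ids), values=values)


def simulate_null(
    p: float,
    n_reads: int,
    n_cpgs: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> RegionMatrix:
    """iid Bernoulli(p) matrix with iid missingness — the no-structure null."""
    if rng is None:
        rng = np.random.default_rng(seed)
    values = (rng.random((n_reads, n_cpgs)) < p).astype(np.int8)
    if missing_rate > 0:
        values[rng.random((n_reads, n_cpgs)) < missing_rate] = MISSING
    return RegionMatrix(
        bin=synthetic_bin(n_cpgs),
        row_ids=[f"read{i}" for i in range(n_reads)],
        values=values,
    )


def matrix_to_fragments(matrix: RegionMatrix) -> list[MethFragment]:
    """Export a region matrix as methylation recordings on its bin's contig."""
    frags = []
    positions = matrix.bin.cpg_positions
    for rid, row in zip(matrix.row_ids, matrix.values):
        obs = tuple(
            (positions[j], int(row[j])) for j in range(len(positions)) if row[j] != MISSING
        )
        if obs:
            frags.append(
                MethFragment(
                    fragment_id=rid, chromosome=matrix.bin.chromosome, observations=obs
                )
            )
    return frags
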