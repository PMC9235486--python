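"""Read-level methylation recordings and their conversion from alignments.

A *methylation recording* is the minimal read-level representation of a
bisulfite experiment: for each sequenced fragment (a single-end read or a
merged read pair), the CpG sites it observed and the binary methylation
state at each. Bismark-style alignments carry this information in the XM
per-base call string ('Z' = methylated CpG, 'z' = unmethylated CpG); this
module extracts it, merges mate pairs, and reads/writes a plain-text
recording format.

The recording format is tab-separated text, one line per fragment::

    #methcon-record\tv1
    <fragment_id>\t<chromosome>\t<pos1,pos2,...>\t<state1,state2,...>

with 1-based forward-strand C positions, states 1 = methylated and
0 = unmethylated, and transparent gzip compression for ``.gz`` paths.
A CpG a fragment did not observe is simply absent — there is no third
state.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

FORMAT_HEADER = "#methcon-record\tv1"

METH = 1
UNMETH = 0


@dataclass(frozen=True)
class MethFragment:
    """One fragment's CpG methylation observations on one chromosome.

    ``observations`` is an ordered tuple of ``(position, state)`` pairs:
    1-based forward-strand C positions, strictly ascending, with state
    1 = methylated, 0 = unmethylated.
    """

    fragment_id: str
    chromosome: str
    observations: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        obs = self.observations
        for i in range(len(obs) - 1):
            if obs[i][0] >= obs[i + 1][0]:
                raise ValueError(
                    f"observations of {self.fragment_id!r} not strictly ascending"
                )
        if any(state not in (METH, UNMETH) for _, state in obs):
            raise ValueError("states must be 0 or 1")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.observations)

    def overlaps(self, start: int, end: int) -> bool:
        """True if any observation falls in the 0-based half-open [start, end)."""
        return any(start <= p - 1 < end for p, _ in self.observations)


class SortOrderError(ValueError):
    """Input alignments were not sorted by read ID."""


@dataclass
class ParseStats:
    """Bookkeeping for one conversion run; output + skips == input templates."""

    templates: int = 0
    fragments: int = 0
    skipped_no_tag: int = 0
    skipped_zero_observations: int = 0
    skipped_mate_chromosome_mismatch: int = 0

    @property
    def skipped(self) -> int:
        return (
            self.skipped_no_tag
            + self.skipped_zero_observations
            + self.skipped_mate_chromosome_mismatch
        )


def _call_strand(read) -> str:
    """'CT' if the methylation call sits on the forward-strand C, 'GA' if on the G.

    Bismark records the genome conversion in the XG tag; without it the
    directional-protocol convention is inferred from the flags.
    """
    if read.has_tag("XG"):
        return read.get_tag("XG")
    reverse = bool(read.is_reverse)
    if read.is_paired and read.is_read2:
        reverse = not reverse
    return "GA" if reverse else "CT"


def _read_observations(read) -> dict[int, int] | None:
    """CpG observations {1-based C position: state} for one aligned read.

    Returns None when the read has no XM-style methylation call string.
    Only query bases aligned to a reference base contribute (insertions and
    soft-clips carry no reference position; deletions carry no call).
    """
    if not read.has_tag("XM"):
        return None
    xm = read.get_tag("XM")
    strand = _call_strand(read)
    obs: dict[int, int] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        ch = xm[qpos]
        if ch == "Z" or ch == "z":
            c_pos = rpos + 1 if strand == "CT" else rpos  # 1-based forward C
            obs[c_pos] = METH if ch == "Z" else UNMETH
    return obs


def merge_mates(obs1: dict[int, int], obs2: dict[int, int]) -> dict[int, int]:
    """Union of two mates' observations; conflicting positions become missing.

    A position observed by both mates with agreeing states appears once; a
    position where the mates disagree is removed entirely (no majority or
    quality vote — the conservative choice for overlapping mate ends).
    """
    merged = dict(obs1)
    for pos, state in obs2.items():
        if pos in merged:
            if merged[pos] != state:
                del merged[pos]
        else:
            merged[pos] = state
    return merged


def parse_alignments(
    alignment_source,
    stats: ParseStats | None = None,
) -> Iterator[MethFragment]:
    """Convert queryname-sorted Bismark-style SAM/BAM into MethFragments.

    Parameters
    ----------
    alignment_source
        Path to a SAM/BAM file or an open :class:`pysam.AlignmentFile`.
        Must be sorted by read ID; single-end and paired-end records may
        be mixed. Secondary, supplementary and unmapped records are
        ignored.
    stats
        Optional :class:`ParseStats` to fill in.

    Yields one fragment per template; templates whose reads carry no
    methylation call string, or no CpG observation, are skipped and
    counted. A read ID recurring after its group has closed raises
    :class:`SortOrderError`.
    """
    import pysam

    if stats is None:
        stats = ParseStats()
    own = not isinstance(alignment_source, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignment_source), check_sq=False)
        if own
        else alignment_source
    )
    try:
        seen: set[str] = set()
        group_name: str | None = None
        group: list = []

        def flush() -> MethFragment | None:
            stats.templates += 1
            per_mate = [(r, _read_observations(r)) for r in group]
            per_mate = [(r, o) for r, o in per_mate if o is not None]
            if not per_mate:
                stats.skipped_no_tag += 1
                return None
            chroms = {r.reference_name for r, _ in per_mate}
            if len(chroms) > 1:
                stats.skipped_mate_chromosome_mismatch += 1
                return None
            obs = per_mate[0][1]
            for _, other in per_mate[1:]:
                obs = merge_mates(obs, other)
            if not obs:
                stats.skipped_zero_observations += 1
                return None
            stats.fragments += 1
            return MethFragment(
                fragment_id=group_name,
                chromosome=next(iter(chroms)),
                observations=tuple(sorted(obs.items())),
            )

        for read in af:
            if read.is_secondary or read.is_supplementary or read.is_unmapped:
                continue
            name = read.query_name
            if name != group_name:
                if name in seen:
                    raise SortOrderError(
                        f"input not sorted by read ID: {name!r} recurs after its group"
                    )
                if group:
                    frag = flush()
                    if frag is not None:
                        yield frag
                    seen.add(group_name)
                group_name = name
                group = []
            group.append(read)
        if group:
            frag = flush()
            if frag is not None:
                yield frag
    finally:
        if own:
            af.close()


def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"))
    return open(path, mode)


def write_records(fragments: Iterable[MethFragment], path) -> int:
    """Write fragments to a recording file; returns the number written."""
    n = 0
    with _open_text(path, "w") as fh:
        fh.write(FORMAT_HEADER + "\n")
        for frag in fragments:
            positions = ",".join(str(p) for p in frag.positions)
            states = ",".join(str(s) for _, s in frag.observations)
            fh.write(f"{frag.fragment_id}\t{frag.chromosome}\t{positions}\t{states}\n")
            n += 1
    return n


def read_records(
    path, region: tuple[str, int, int] | None = None
) -> Iterator[MethFragment]:
    """Stream fragments from a recording file.

    ``region`` is ``(chromosome, start, end)`` half-open 0-based; only
    fragments with at least one observation inside it are yielded.
    Malformed lines raise ValueError with the line number.
    """
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed record at line {lineno}")
            frag_id, chrom, pos_s, state_s = parts
            try:
                positions = [int(p) for p in pos_s.split(",")]
                states = [int(s) for s in state_s.split(",")]
                if len(positions) != len(states):
                    raise ValueError
                frag = MethFragment(
                    fragment_id=frag_id,
                    chromosome=chrom,
                    observations=tuple(zip(positions, states)),
                )
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed record at line {lineno}"
                ) from exc
            if region is not None:
                chrom_q, start, end = region
                if frag.chromosome != chrom_q or not frag.overlaps(start, end):
                    continue
            yield frag
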