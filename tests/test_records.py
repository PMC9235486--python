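"""Alignment -> recording conversion and the recording file format."""

import numpy as np
import pytest

from methcon.records import (
    MethFragment,
    ParseStats,
    SortOrderError,
    merge_mates,
    parse_alignments,
    read_records,
    write_records,
)

HEADER = "@HD\tVN:1.6\tSO:queryname\n@SQ\tSN:chr1\tLN:10000\n"


def sam_line(qname, flag, pos, seq, xm, xg="CT", rname="chr1", cigar=None):
    cigar = cigar or f"{len(seq)}M"
    tags = f"XM:Z:{xm}\tXG:Z:{xg}"
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t42\t{cigar}\t*\t0\t0\t{seq}\t"
        f"{'I' * len(seq)}\t{tags}\n"
    )


def write_sam(tmp_path, lines, name="in.sam"):
    path = tmp_path / name
    path.write_text(HEADER + "".join(lines))
    return path


class TestParseAlignments:
    def test_single_end_forward_xm_walk(self, tmp_path):
        """XM '..z...Z.' at 1-based pos 101 -> unmeth C at 103, meth C at 107."""
        sam = write_sam(tmp_path, [sam_line("r1", 0, 101, "TTCATTCG", "..z...Z.")])
        frags = list(parse_alignments(sam))
        assert len(frags) == 1
        assert frags[0].chromosome == "chr1"
        assert frags[0].observations == ((103, 0), (107, 1))

    def test_read_without_cpg_calls_dropped(self, tmp_path):
        sam = write_sam(tmp_path, [sam_line("r1", 0, 101, "TTTT", "....")])
        stats = ParseStats()
        assert list(parse_alignments(sam, stats=stats)) == []
        assert stats.skipped_zero_observations == 1

    def test_missing_xm_tag_counted(self, tmp_path):
        line = "r1\t0\tchr1\t101\t42\t4M\t*\t0\t0\tTTTT\tIIII\n"
        sam = write_sam(tmp_path, [line])
        stats = ParseStats()
        assert list(parse_alignments(sam, stats=stats)) == []
        assert stats.skipped_no_tag == 1

    def test_strand_normalization_to_forward_c(self, tmp_path):
        """Forward and reverse reads over the same CpG report the same C position."""
        # CpG with C at 1-based 201, G at 202; the GA-strand call sits on the G
        fwd = sam_line("fwd", 0, 199, "TTCT", "..Z.", xg="CT")
        rev = sam_line("rev", 16, 201, "TGTT", ".Z..", xg="GA")
        sam = write_sam(tmp_path, [fwd, rev])
        frags = {f.fragment_id: f for f in parse_alignments(sam)}
        assert frags["fwd"].observations == ((201, 1),)
        assert frags["rev"].observations == ((201, 1),)

    def test_paired_end_merged_to_one_fragment(self, tmp_path):
        m1 = sam_line("p1", 99, 101, "CGTT", "Z...")
        m2 = sam_line("p1", 147, 149, "CGTT", "z...")
        sam = write_sam(tmp_path, [m1, m2])
        frags = list(parse_alignments(sam))
        assert len(frags) == 1
        assert frags[0].observations == ((101, 1), (149, 0))

    def test_mixed_single_and_paired_input(self, tmp_path):
        lines = [
            sam_line("a", 0, 101, "CG", "Z."),
            sam_line("b", 99, 101, "CG", "Z."),
            sam_line("b", 147, 201, "CG", "z."),
            sam_line("c", 0, 301, "CG", "z."),
        ]
        sam = write_sam(tmp_path, lines)
        stats = ParseStats()
        frags = list(parse_alignments(sam, stats=stats))
        assert [f.fragment_id for f in frags] == ["a", "b", "c"]
        assert stats.templates == 3 and stats.fragments == 3

    def test_unsorted_input_raises_naming_read(self, tmp_path):
        lines = [
            sam_line("a", 0, 101, "CG", "Z."),
            sam_line("b", 0, 201, "CG", "Z."),
            sam_line("a", 0, 301, "CG", "z."),
        ]
        sam = write_sam(tmp_path, lines)
        with pytest.raises(SortOrderError, match="'a'"):
            list(parse_alignments(sam))

    def test_output_plus_skips_equals_templates(self, tmp_path, rng):
        lines = []
        for i in range(30):
            if i % 3 == 0:
                lines.append(sam_line(f"r{i:03d}", 0, 101 + i, "TTTT", "...."))
            else:
                lines.append(sam_line(f"r{i:03d}", 0, 101 + i, "CGTT", "Z..."))
        sam = write_sam(tmp_path, lines)
        stats = ParseStats()
        frags = list(parse_alignments(sam, stats=stats))
        assert len(frags) + stats.skipped == stats.templates == 30


class TestMergeMates:
    def test_agreeing_overlap_collapses(self):
        assert merge_mates({103: 1}, {103: 1, 150: 0}) == {103: 1, 150: 0}

    def test_conflicting_overlap_removed(self):
        assert merge_mates({103: 1}, {103: 0}) == {}

    def test_disjoint_union(self):
        assert merge_mates({103: 1}, {250: 0}) == {103: 1, 250: 0}


def random_fragments(rng, n=100):
    frags = []
    for i in range(n):
        n_obs = int(rng.integers(1, 9))
        positions = np.sort(rng.choice(np.arange(1, 2000), size=n_obs, replace=False))
        states = rng.integers(0, 2, size=n_obs)
        frags.append(
            MethFragment(
                fragment_id=f"f{i}",
                chromosome=str(rng.choice(["chr1", "chr2"])),
                observations=tuple((int(p), int(s)) for p, s in zip(positions, states)),
            )
        )
    return frags


class TestRecordingFormat:
    @pytest.mark.parametrize("suffix", ["rec.tsv", "rec.tsv.gz"])
    def test_round_trip_identity(self, tmp_path, rng, suffix):
        frags = random_fragments(rng)
        path = tmp_path / suffix
        assert write_records(frags, path) == len(frags)
        back = list(read_records(path))
        assert back == frags

    def test_empty_file_has_header(self, tmp_path):
        path = tmp_path / "empty.rec"
        write_records([], path)
        assert path.read_text().startswith("#methcon-record")
        assert list(read_records(path)) == []

    def test_region_query_matches_linear_scan(self, tmp_path, rng):
        frags = random_fragments(rng, n=200)
        path = tmp_path / "r.rec"
        write_records(frags, path)
        region = ("chr1", 450, 600)
        got = list(read_records(path, region=region))
        want = [
            f
            for f in frags
            if f.chromosome == "chr1" and f.overlaps(450, 600)
        ]
        assert got == want

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.rec"
        path.write_text("#methcon-record\tv1\nf1\tchr1\t10\n")
        with pytest.raises(ValueError, match="line 2"):
            list(read_records(path))

    def test_fragment_invariants_enforced(self):
        with pytest.raises(ValueError):
            MethFragment("f", "chr1", ((10, 1), (10, 0)))
        with pytest.raises(ValueError):
            MethFragment("f", "chr1", ((10, 2),))
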