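"""Concordance core: matrix-product counts, normalization, binomial tails."""

import math

import numpy as np
import pytest

from methcon.concord import (
    binomial_pvalue,
    build_indicators,
    concordance,
    cpgs_axis_counts,
    reads_axis_counts,
    score_region,
)

import oracle


def _counts_tuple(ac):
    return (
        ac.concordant_meth_pairs,
        ac.concordant_unmeth_pairs,
        ac.valid_pairs,
        ac.pooled_meth,
        ac.pooled_unmeth,
    )


class TestIndicators:
    def test_definition_on_mixed_matrix(self):
        values = np.array([[1, -1], [0, 1]], dtype=np.int8)
        ind = build_indicators(values)
        assert ind.M.tolist() == [[1, 0], [0, 1]]
        assert ind.N.tolist() == [[0, 0], [1, 0]]
        assert ind.T.tolist() == [[1, 0], [1, 1]]

    def test_invariants_on_random_matrices(self, random_matrices):
        for values in random_matrices[:50]:
            ind = build_indicators(values)
            assert (ind.M * ind.N == 0).all()
            assert (ind.M + ind.N == ind.T).all()


class TestAxisCounts:
    def test_worked_example_reads_axis(self, worked_matrix):
        ac = reads_axis_counts(build_indicators(worked_matrix))
        # doubled off-diagonal counts: 2 concordant-meth, 2 concordant-unmeth,
        # 12 valid site comparisons
        assert _counts_tuple(ac) == (2, 2, 12, 6, 6)

    def test_worked_example_cpgs_axis(self, worked_matrix):
        ac = cpgs_axis_counts(build_indicators(worked_matrix))
        assert _counts_tuple(ac) == (2, 2, 6, 3, 3)

    def test_identical_fully_methylated_reads(self):
        values = np.ones((2, 5), dtype=np.int8)
        ac = reads_axis_counts(build_indicators(values))
        assert _counts_tuple(ac)[:3] == (10, 0, 10)
        raw, _, _, _ = concordance(ac)
        assert raw == 1.0

    def test_single_read_gives_zero_counts(self):
        ac = reads_axis_counts(build_indicators(np.ones((1, 5), dtype=np.int8)))
        assert _counts_tuple(ac) == (0, 0, 0, 0, 0)

    def test_pair_agreeing_at_5_of_8_shared_sites(self):
        a = np.array([1, 1, 0, 0, 1, 0, 1, 0])
        b = a.copy()
        b[[2, 4, 7]] = 1 - b[[2, 4, 7]]
        ac = reads_axis_counts(build_indicators(np.vstack([a, b])))
        raw, _, _, _ = concordance(ac)
        assert raw == pytest.approx(5 / 8)


class TestOracleEquivalence:
    def test_counts_match_bruteforce_both_axes(self, random_matrices):
        for values in random_matrices:
            ind = build_indicators(values)
            for fn, axis in ((reads_axis_counts, "reads"), (cpgs_axis_counts, "cpgs")):
                got = _counts_tuple(fn(ind))
                want = oracle.pairwise_counts(values, axis)
                assert got == (
                    want["m"],
                    want["n"],
                    want["t"],
                    want["pooled_m"],
                    want["pooled_u"],
                )

    def test_scores_match_oracle_pipeline(self, random_matrices):
        for values in random_matrices[:60]:
            s = score_region(values)
            o = oracle.score(values)
            for got, want in (
                (s.rc, o["raw_r"]),
                (s.cc, o["raw_c"]),
                (s.nrc, o["nrm_r"]),
                (s.ncc, o["nrm_c"]),
                (s.p_reads, o["p_r"]),
                (s.p_cpgs, o["p_c"]),
            ):
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestConcordanceNormalization:
    def test_worked_example_normalized(self, worked_matrix):
        s = score_region(worked_matrix)
        assert s.rc == pytest.approx(1 / 3)
        assert s.cc == pytest.approx(2 / 3)
        assert s.pr_hat == pytest.approx(0.5)
        assert s.er == pytest.approx(0.5)
        assert s.nrc == pytest.approx(-1 / 6)

    def test_expected_concordance_at_quarter(self):
        from methcon.concord import AxisCounts

        # pooled level 0.25 -> e = 0.0625 + 0.5625
        ac = AxisCounts(0, 0, 4, 1, 3)
        _, p, e, _ = concordance(ac)
        assert p == 0.25 and e == pytest.approx(0.625)

    def test_degenerate_all_methylated(self):
        s = score_region(np.ones((4, 4), dtype=np.int8))
        assert s.rc == 1.0 and s.er == 1.0 and s.nrc == 0.0
        assert s.p_reads == 1.0

    def test_no_valid_pairs_gives_nan(self):
        from methcon.concord import AxisCounts

        raw, p, e, nrm = concordance(AxisCounts(0, 0, 0, 0, 0))
        assert all(math.isnan(x) for x in (raw, p, e, nrm))


class TestBinomialPvalue:
    def test_spec_example_lower_tail(self):
        p, _ = binomial_pvalue(2, 6, 0.5)
        assert p == pytest.approx(22 / 64, abs=1e-15)

    def test_upper_tail_closed_form(self):
        p, _ = binomial_pvalue(4, 4, 0.5)
        assert p == pytest.approx(0.5**4, abs=1e-15)

    @pytest.mark.parametrize("e", [0.5, 0.625, 0.9])
    def test_matches_explicit_pmf_summation(self, e):
        for t in range(1, 31):
            for obs in range(t + 1):
                p, _ = binomial_pvalue(obs, t, e)
                assert p == pytest.approx(oracle.binom_tail(obs, t, e), rel=1e-10)

    def test_boundary_uses_upper_tail(self):
        # observed == t*e exactly: the >= branch
        p, _ = binomial_pvalue(3, 6, 0.5)
        want = sum(oracle.binom_tail(i, 6, 0.5) - oracle.binom_tail(i - 1, 6, 0.5) for i in [3])
        assert p == pytest.approx(oracle.binom_tail(3, 6, 0.5))

    def test_degenerate_expectation_gives_one(self):
        assert binomial_pvalue(5, 5, 1.0)[0] == 1.0
        assert binomial_pvalue(0, 5, 0.0)[0] == 1.0

    def test_zero_trials_gives_nan(self):
        assert math.isnan(binomial_pvalue(0, 0, 0.5)[0])

    def test_finite_nonzero_at_million_trials(self):
        t = 10**6
        p, log_p = binomial_pvalue(t, t, 0.5)
        assert 0.0 < p <= 1.0
        assert math.isfinite(log_p) and log_p == pytest.approx(t * math.log(0.5))


class TestScoreRegion:
    def test_row_and_column_permutation_invariance(self, rng, random_matrices):
        for values in random_matrices[:20]:
            s = score_region(values)
            perm = values[rng.permutation(values.shape[0])][:, rng.permutation(values.shape[1])]
            sp = score_region(perm)
            for a, b in ((s.rc, sp.rc), (s.cc, sp.cc), (s.nrc, sp.nrc), (s.ncc, sp.ncc)):
                if math.isnan(a):
                    assert math.isnan(b)
                else:
                    assert a == pytest.approx(b, abs=1e-14)

    def test_single_read_matrix_reads_axis_nan(self):
        s = score_region(np.array([[1, 0, 1]], dtype=np.int8))
        assert math.isnan(s.rc) and math.isnan(s.nrc) and math.isnan(s.p_reads)
        assert not math.isnan(s.cc)

    def test_raw_scores_minimized_near_half_methylation(self, rng):
        """RC and CC are biased low toward methylation level 0.5."""
        mean_rc = {}
        for p in (0.1, 0.5, 0.9):
            vals = [
                score_region((rng.random((12, 8)) < p).astype(np.int8)).rc
                for _ in range(150)
            ]
            mean_rc[p] = np.nanmean(vals)
        assert mean_rc[0.5] < mean_rc[0.1]
        assert mean_rc[0.5] < mean_rc[0.9]

    def test_high_coverage_capability(self):
        import time

        rng = np.random.default_rng(5)
        values = (rng.random((2000, 8)) < 0.3).astype(np.int8)
        t0 = time.perf_counter()
        s = score_region(values)
        assert time.perf_counter() - t0 < 10.0
        assert math.isfinite(s.nrc) and math.isfinite(s.ncc)
        assert s.reads_axis.valid_pairs == 2000 * 1999 * 8
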