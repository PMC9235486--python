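# Methods

## Model

A genomic bin is summarized by a ternary reads × CpG-sites matrix:
each sequenced fragment (single-end read or merged read pair) is a row,
each CpG site in the bin a column, and each cell is methylated,
unmethylated or missing. Two pooled concordance statistics are computed
from the binary indicators `M` (methylated), `N` (unmethylated) and
`T = M + N` (covered):

* **Reads concordance** `RC = (mr + nr) / tr`, where `mr`, `nr` and
  `tr` are the off-diagonal sums of `M·Mᵀ`, `N·Nᵀ` and `T·Tᵀ` — over
  every ordered pair of reads, the number of jointly covered sites at
  which both are methylated, both unmethylated, or covered at all.
  `RC` is one minus the pooled normalized Hamming distance between
  reads, and equals `1 − qFDRP` identically.
* **CpGs concordance** `CC = (mc + nc) / tc` from the transposed
  products: the same quantity over ordered pairs of CpG sites,
  measuring co-methylation of neighbouring sites within reads.

The off-diagonal sums count each unordered pair twice. The doubled
counts are kept deliberately — the ratios are unchanged and the integer
counts exported with `--counts` are the doubled values.

**Normalization.** Raw concordance depends on the methylation level: at
pooled level `p`, two independent draws agree with probability
`e = p² + (1 − p)²`, minimized (0.5) at `p = 0.5`. Each axis's pooled
level is estimated from its own comparisons
(`p_r = mpr / (mpr + npr)`, with `mpr`, `npr` the off-diagonal sums of
`T·Mᵀ` and `T·Nᵀ`), giving `NRC = RC − e_r` and `NCC = CC − e_c`.
A normalized score near zero means "no more concordant than independent
draws at this methylation level"; positive scores mean excess structure.

**Significance.** `Pr` (and `Pc`) is the exact one-sided binomial tail
on the concordant count: lower tail when `mr + nr < tr·e_r`, upper tail
otherwise (the boundary uses the upper tail), never doubled. This
treats the doubled, mutually dependent pair comparisons as independent
Bernoulli trials, so the p-values are a ranking device rather than
calibrated tail probabilities: under an iid null their distribution is
not uniform (anti-conservative near methylation 0.5, conservative at
extreme levels). The pattern classifier therefore thresholds them at
extreme cutoffs (1e−10 / 1e−5) where the ordering, not the calibration,
matters. Users should not interpret `Pr`/`Pc` as type-I-error-calibrated
tests.

## Pattern classification

With the default thresholds (all configurable):

| pattern    | rule                                              |
|------------|---------------------------------------------------|
| uniform    | NCC > 0.1 and NRC < 0.1 and Pc < 1e−10            |
| identical  | NRC > 0.1 and NCC < 0.1 and Pr < 1e−10            |
| disordered | NCC < 0.1 and NRC < 0.1 and Pr > 1e−5 and Pc > 1e−5 |

All inequalities are strict, which makes the three rules mutually
exclusive; anything else is *ambiguous* (including the
both-scores-high corner, which is never forced into a canonical class)
and undefined scores give *insufficient*. The disordered rule requires
both p-values to be unremarkable, and the significant p-value for
uniform/identical belongs to the concordant axis (Pc for uniform, Pr
for identical) — the symmetric, conservative reading.

Bins enter classification only after the coverage filters: at least 6
CpG sites and at least 6 mapped reads ("more than 5" read strictly),
and, for genome-wide scans, an intermediate mean methylation
(0.05 < mean < 0.95). Mean methylation is cell-weighted
(methylated cells / covered cells), so deeply covered CpGs weigh more;
a per-CpG-averaged alternative was not adopted.

## Conversion and binning

Bismark-style XM call strings ('Z'/'z' at CpGs) are mapped to reference
coordinates through the alignment; calls on the reverse strand (XG
'GA') sit on the G and are shifted by −1 so every CpG is identified by
the 1-based forward-strand C. Input must be queryname-sorted; mates of
a pair are merged by union, and a site the two mates call differently
is dropped to missing rather than voted — conservative, at the cost of
a little coverage. Reads with indels contribute an observation only
where a query base is aligned to the reference position. The recording
file format is tab-separated text (fragment id, chromosome,
comma-joined positions, comma-joined states), gzip-transparent, with a
versioned header.

Bins tile each chromosome from its origin in 150-bp windows (the width
of a typical short read; configurable), the last partial window kept if
it passes the CpG filter; a CpG belongs to the window containing its C.
A user BED can replace the tiling. For the CpG-island screen, islands
are intersected with the same origin-aligned tiling and clipped pieces
are kept when they retain ≥ 6 CpGs.

## Hypermethylation screen

Per bin and sample a mean methylation level is computed; bins with
control mean < 0.20 and control sample SD < 0.05 (n−1 denominator,
suited to the typical 3 replicates) are the stable-low background, and
a case sample gains a bin when its level exceeds the control mean by
more than 0.1 (strict). Cases are called independently. A bin is
evaluable only when all control values and the case value are defined.
Pattern composition of the gained bins then distinguishes uniform
(clonal/population-level) from disordered (stochastic) gains.

## Simulator

The simulator generates the benchmark conditions used by the tests:
12 reads × 8 CpGs, target methylation 0.25, and 5% random state flips
as the noise model. P1 (identical) is a deterministic footprint —
`round(0.25·c)` methylated columns, evenly interspersed, identical
across reads; P3 (disordered) is iid Bernoulli(0.25); P5 (uniform)
draws each read all-methylated with probability 0.25. P2/P4 are 50/50
column-/row-wise mixtures of their flanking patterns; they are
API-filling only (they are not canonical patterns) and excluded from
the headline properties. Noise is a symmetric flip of non-missing
cells; no strand- or conversion-asymmetric error model is attempted.
The null generator draws iid Bernoulli(p) states with iid missingness.

What the simulator does *not* emulate: read-length and fragment-size
structure, per-CpG coverage gradients, bisulfite conversion failure
profiles, allele linkage across bins, or mapping artefacts. Passing
the recovery tests therefore shows the metrics separate the pattern
archetypes under clean sampling noise, not that they are immune to
alignment- or chemistry-induced biases in real libraries.

## Numerical choices

* Pair counts use 64-bit integers throughout (`tr` grows as `r²·c`;
  2000 reads × 8 CpGs gives ~3.2e7 doubled comparisons).
* Binomial tails use scipy's linear-space cdf/sf; when the tail
  underflows double precision (possible at ~1e6 trials), an exact
  log-space summation of log-pmf terms takes over. The returned
  p-value is floored at the smallest positive normal double so it
  stays in (0, 1]; the exact natural-log tail is exposed as
  `log_p_reads` / `log_p_cpgs`.
* Degenerate expectation (`e` = 0 or 1, i.e. pooled counts all one
  state): the binomial is degenerate, so the p-value is defined as 1
  and the normalized score as `raw − e` — continuous and conservative.
* No valid pairs (single read, single CpG, or disjoint coverage):
  scores and p-values are NaN and propagate to the *insufficient*
  label; no exception is raised.
* No multiple-testing correction is applied anywhere in the
  classifier; raw p-values are thresholded.

## Problem sizes

The test suite and `scripts/acceptance.py` use 200 random matrices
(≤ 15 reads × ≤ 10 CpGs, up to 50% missing) for the dual-route exact
checks, 2000 null matrices (20 × 8) per methylation level for
calibration summaries, 200 replicates per pattern at 100 × 8 (5%
noise) for recovery rates, 200 seeds at 12 × 8 for the score-ordering
geometry, 100 seeds per pattern for the noise-shift comparison, one
2000 × 8 matrix for the high-coverage check, and an 80-bin, 3-control
synthetic cohort (100 reads/bin, 20% of case bins shifted from
Bernoulli 0.1 to uniform-structured 0.35) for the hypermethylation
screen. These sizes were chosen as the smallest at which the binomial
sampling error of each summary is well below its decision margin.

## Known limitations

* CpG methylation only; CHH/CHG calls are ignored.
* The binomial p-values are uncalibrated by construction (see above).
* The score-table pipeline loads a recording file into memory per
  chromosome; it targets per-region studies and test-scale genomes,
  not streaming whole-genome recordings.
* Mate-conflict handling and the P2/P4 constructions are this
  package's own choices where the field has no fixed convention.
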