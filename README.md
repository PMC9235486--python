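# methcon

Read-level DNA methylation concordance across reads and CpG sites.

Intermediately methylated regions (mean methylation between 0.05 and
0.95) make up a large fraction of a mammalian genome, and the same mean
methylation level can arise from very different read-level patterns: an
*identical* footprint shared by all molecules, a *uniform* split into
fully methylated and fully unmethylated reads (allele-specific
methylation, cell-type mixtures), or *disordered* stochastic methylation.
`methcon` quantifies these patterns for bisulfite-sequencing data
(WGBS/RRBS) with a pair of Hamming-distance concordance metrics, one per
axis of the reads × CpG-sites matrix, and classifies genomic bins into
the three patterns. It is aimed at anyone doing read-level methylome
analysis: epigenomics researchers screening for allele-specific or
eroded regions, and method developers who need a noise-robust
heterogeneity score.

## The metrics

For a bin, build binary indicator matrices from the ternary
reads × CpG-sites matrix: `M` (methylated), `N` (unmethylated),
`T = M + N` (covered), with `r` reads and `c` CpG sites. Off-diagonal
sums of symmetric products count state-agreements over every ordered
pair of reads:

    mr = Σ (M·Mᵀ ⊙ (U − I)),  nr = Σ (N·Nᵀ ⊙ (U − I)),  tr = Σ (T·Tᵀ ⊙ (U − I))
    RC = (mr + nr) / tr                      (reads concordance)

and transposed products give `mc, nc, tc` and `CC` over pairs of CpG
sites (CpGs concordance). Both raw scores are biased by the methylation
level (lowest near 0.5), so each is normalized by the concordance
expected from the pooled methylation level `p` of its own comparisons:

    e = p² + (1 − p)²,   NRC = RC − e_r,   NCC = CC − e_c

with an exact one-sided binomial tail (`Pr`, `Pc`) on the concordant
count as significance. Bins are labeled with the default cutoffs
uniform: NCC > 0.1, NRC < 0.1, Pc < 1e−10; identical: NRC > 0.1,
NCC < 0.1, Pr < 1e−10; disordered: both scores < 0.1 and both p-values
> 1e−5. The matrix-product formulation scores bins with well over 1000
reads without subsampling, and reads concordance is exactly the
complement of qFDRP (1 − RC).

## Worked example

```python
import numpy as np
from methcon import MethylationConcordance

# 3 reads x 2 CpGs: rows MM, MU, UU (1 = methylated, 0 = unmethylated)
res = MethylationConcordance(np.array([[1, 1], [1, 0], [0, 0]])).fit()
print(res.summary())
```

```
Methylation concordance
=======================================================
region           sim:0-150
reads / CpGs     3 / 2
mean methylation 0.5000
-------------------------------------------------------
                      reads axis     CpGs axis
raw concordance           0.3333        0.6667
pooled meth p             0.5000        0.5000
expected                  0.5000        0.5000
normalized               -0.1667        0.1667
P-value                1.938e-01     3.437e-01
-------------------------------------------------------
pattern          ambiguous
```

Reads agree at 4 of 12 pairwise site comparisons (RC = 1/3) while
columns agree at 4 of 6 (CC = 2/3); at a pooled methylation level of
0.5 the expected concordance is 0.5, so NRC = −1/6 and NCC = +1/6, and
with only three reads neither deviation is significant — the bin stays
unlabeled. The same scores come from the shell pipeline:

```bash
methcon simulate --pattern P5 --reads 100 --noise 0.05 --seed 1 --out p5.rec
methcon score --rec p5.rec --fasta ref.fa --out scores.tsv
methcon classify --scores scores.tsv --out labeled.tsv
methcon plot --rec p5.rec --region sim:0-150 --out region.pdf
```

`methcon bam2record` converts queryname-sorted Bismark-style SAM/BAM
(XM call strings) into the plain-text recording format the scorer
reads, and `methcon cgi-dmr` screens CpG-island bins for case-sample
hypermethylation and summarizes the pattern composition of the gains.

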