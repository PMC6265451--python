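# polterm

Quantitative analysis of Pol II 3′-end processing factor occupancy on mRNA
versus sn/snoRNA genes, for functional-genomics researchers comparing
cleavage-and-polyadenylation (CPF-like) machinery with the APT complex.
The package implements four analysis arms as a tested, reusable library,
together with a seeded synthetic-data generator that plants ground truth
for every stage:

- **ChIP-seq occupancy** — paired-end *physical coverage* (fragments
  spanning both mates and the unsequenced insert, MAPQ ≥ 7, proper pairs
  only), replicate averaging, signal-extraction-scaling (SES) of input,
  enrichment `log2(IP / sf·input)`, and conversion to percent occupancy by
  anchoring the genome-wide 99.8% and 10% enrichment quantiles at 100% and
  0%, followed by ±50 bp sliding-window smoothing.
- **PAR-CLIP crosslink sites** — T positions with an excess of T→C
  transition reads over a binomial error null,
  `p = P(X ≥ k | n, p_err)`, with `p_err` estimated from mismatch types
  that cannot be crosslink-induced; sites require `p ≤ 0.005` and coverage
  ≥ 2. Occupancies are normalized by a smoothed Pol II expression track.
- **Metagene statistics** — per-gene signal aligned at the TSS and
  length-scaled so all pA sites coincide (100 body bins, 200 bp flanks),
  gene-wise 98%-quantile occupancy over the body + 100 bp downstream,
  joint min–max scaling of two class profiles, two-sided Mann–Whitney U
  class comparisons, and Tukey boxplot summaries.
- **4tU-seq differential synthesis** — median-of-ratios size factors, a
  ≥ 30 average-normalized-count expression filter (in either condition), a
  negative-binomial Wald test of knockout vs wild type (moment dispersion
  shrunk toward a 1/µ trend; unshrunken fold changes), Benjamini–Hochberg
  adjustment, |FC| > 1.5 & padj < 0.1 calls, Fisher's exact test for
  sn/snoRNA enrichment among calls, and the median class fold shift
  `2^(median log2FC_mRNA − median log2FC_sn/snoRNA)`.

Annotation handling (BED6/GFF3, isolation and class-overlap filters) and
bedGraph/SAM/TSV I/O round out the pipeline; `polterm.pipeline.run_pipeline`
runs everything end to end on the synthetic preset.

## Worked example

`examples/` contains one short script per capability. The differential-
synthesis example plants a 3-fold sn/snoRNA reduction (2 vs 2 replicates,
NB dispersion 0.05) and recovers it:

```
$ python examples/05_diff_synthesis.py
count matrix: 332 genes x 4 samples
size factors: [1.025, 1.203, 0.767, 1.065] (planted library sizes: [1.0, 1.2, 0.8, 1.1] )
mRNA: 281 tested, 8 down, 20 up
snsnoRNA: 30 tested, 27 down, 0 up
sn/snoRNA enrichment among down-regulated genes: OR=307.1, Fisher p=1.52e-28
median class fold shift (mRNA vs sn/snoRNA): 3.05 (planted: 3.0)
```

The estimated size factors track the planted library sizes, 27/30
sn/snoRNAs are called down at the FC 1.5 / padj 0.1 thresholds while
mRNA calls stay near their planted 2%/5% rates, and the median class
shift recovers the planted 3-fold reduction.

`python examples/06_full_pipeline.py out/` runs the complete synthetic
study (~15 s) and prints the recovery summary for all three data types.

A thin CLI mirrors the library (`polterm simulate | filter-annotations |
coverage | chip-occupancy | parclip-sites | metagene | diffsyn |
compare-classes | run-all`).

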