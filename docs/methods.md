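# Methods

## Scope and data model

The package quantifies where two kinds of Pol II 3′-end processing factors
act — a CPF-like factor expected at mRNA pA sites and an APT-like factor
expected across sn/snoRNA gene bodies — from three complementary assays:
ChIP-seq (DNA occupancy), PAR-CLIP (RNA contacts) and 4tU-seq (RNA
synthesis). All genomic signal is held as per-base float arrays per
chromosome (`CoverageTrack`), 0-based half-open coordinates internally;
GFF3 I/O is 1-based closed and BED 0-based half-open. Strand-aware signals
(PAR-CLIP, expression) are pairs of tracks, one per strand; ChIP physical
coverage is unstranded because sonicated chromatin carries no strand
information.

## Annotation filters

Class comparisons require genes whose signal is attributable to one locus.
Two filters define the analysis sets:

- **Isolation**: a transcript is kept iff the distance between its
  annotated interval and every neighbour (same strand for RNA-side
  analyses, both strands for ChIP) is at least `min_gap` (150 nt / 200 bp
  defaults). Distance is between end-exclusive interval boundaries, so a
  bookended pair has gap 0 and overlapping transcripts always fail; this
  is the most conservative reading of "away from neighboring transcripts".
- **Class overlap**: every overlapping mRNA/sn-snoRNA pair (either strand)
  is removed entirely — e.g. an intronic snoRNA removes both itself and
  its host, since neither signal could be assigned to a class.

Isolation runs first, then class-overlap exclusion; the two commute on all
layouts we generate, but the order is fixed for reproducibility.

## ChIP occupancy

Fragments are reconstructed from proper pairs (SAM flags 99/147/83/163)
where both mates reach MAPQ 7; *physical coverage* counts, per base, the
fragments spanning it, including the unsequenced insert. Replicates are
averaged per position.

**SES scaling.** IP and input libraries differ in depth and signal
fraction, so the input is rescaled to match the IP in background regions.
Windows of 100 bp are sampled (100 000 seeded draws with replacement, or
an exhaustive non-overlapping tiling when `n_bins=None` — the mode used
for deterministic tests) and sorted by ascending IP sum. With cumulative
fractions F_ip(k), F_in(k) over sorted ranks, the background/signal cut is
the **last** rank maximizing F_in − F_ip, and the factor is
(cumulative IP)/(cumulative input) there, applied as a multiplier on the
input. The last-rank tie-break makes the degenerate flat-difference case
(IP ∝ input) collapse to the total-sum ratio instead of an arbitrary —
possibly empty — low-signal bin.

Enrichment is `log2((IP + 1)/(sf·input + 1))`; the unit pseudocount on
both sides guards zero coverage and leaves equal tracks at exactly zero.
Percent occupancy maps enrichment linearly so the genome-wide 10% quantile
(type-7 linear interpolation, used for every quantile in the package) is
0% and the 99.8% quantile is 100%, clamping outside [0, 100] — occupancy
is by definition a 0–100% scale. Smoothing (±50 bp sliding mean, truncated
at chromosome ends, NaN-aware) runs after the occupancy conversion.

## PAR-CLIP site calling

The null hypothesis is that T→C transitions at a T position arise from
sequencing errors and SNPs rather than crosslinks. We estimate a single
global error rate as the pooled rate of *non*-T→C mismatches — mismatch
types that crosslinking cannot produce — floored at 1e-6, and compute the
exact upper binomial tail P(X ≥ k | n, p_err). Sites require p ≤ 0.005,
coverage ≥ 2 and k ≥ 1; no multiplicity adjustment is applied, matching
the deliberately stringent fixed-cutoff design. A position-specific error
model is a straightforward extension point but is not needed at the error
rates simulated here.

Site occupancy is transition reads divided by local RNA concentration,
estimated by a Pol II PAR-CLIP coverage track smoothed with the same ±50
half-window before division. Positions whose smoothed expression falls
below `min_expr = 1` are floored and flagged; flagged positions are
excluded from metagene averages rather than contributing unstable ratios.

## Metagene statistics

Gene bodies are linearly rescaled onto 100 bins (TSS at bin 1, pA at bin
100) with **area-weighted binning**: bin i averages the per-base step
function over the exact real interval [iL/B, (i+1)L/B), so the body mean
is preserved exactly for any gene length, and genes shorter than the bin
count are handled by the same rule. When masked (NaN) positions are
present, bins fall back to means over the finite positions they cover.
Flanks (200 bp default) stay in unscaled bp; minus-strand profiles are
reversed so the left edge is always 5′. The per-gene summary statistic is
the 98% quantile of the smoothed signal over the body plus 100 bp
(strand-oriented) downstream — robust to single positions yet sensitive
to 3′ peaks. Class profile pairs are min–max scaled jointly (joint min →
0, joint max → 1) so shapes can be overlaid without hiding level
differences between the classes.

Class comparisons use the two-sided Mann–Whitney U test: the exact null
distribution when n_a·n_b ≤ 10⁴ and no cross-group ties, otherwise the
normal approximation with midrank tie correction; all-tied inputs return
p = 1. Boxplot summaries are Tukey-style (1.5·IQR whiskers at the most
extreme data points inside the fences).

## 4tU differential synthesis

Per-gene counting is strand-aware union mode at the fragment level: a
fragment counts iff it overlaps exactly one gene interval. Size factors
are median-of-ratios against the geometric-mean pseudo-reference over
genes positive in all samples, with no further rescaling. Genes need ≥ 30
average normalized counts in either condition to enter testing.

The test is a defined NB Wald procedure, not a wrapper around any DE
package, and numeric equivalence with such packages is not claimed:

- normalized counts y = c/s; condition means µ_wt, µ_ko;
- per-gene dispersion by method of moments on *within-condition*
  variability, `α = (s²_within − µ·mean(1/s))/µ²`, floored at 1e-8 and
  shrunk 50/50 toward the cross-gene trend `α(µ) = a0 + a1/µ` fitted by
  least squares — the floor catches under-dispersed moment estimates from
  few replicates, the trend borrows strength across genes;
- `log2FC = log2((µ_ko + c0)/(µ_wt + c0))` with pseudocount
  c0 = 0.5·mean(s); the fold change is not shrunk;
- Wald SE from the NB variance µ + αµ² by the delta method; two-sided
  normal p; Benjamini–Hochberg over all tested genes.

Calls use fold change > 1.5 (either direction) and padj < 0.1. Class
enrichment among calls is the two-sided Fisher exact test on the 2×2
{sn/snoRNA, mRNA} × {called, not} table; the global effect size is the
median class shift `2^(median log2FC_mRNA − median log2FC_sn/snoRNA)`,
oriented so values > 1 mean sn/snoRNAs are more reduced. Under a fully
null 2000-gene simulation this chain keeps the fraction of padj < 0.1
calls below about 0.4%.

## Synthetic data and what it does (not) show

The generator emulates the study design at desk scale: 2 × 1 Mb
chromosomes with 300 mRNAs (500–2000 bp) and 40 sn/snoRNAs (100–600 bp),
intergenic gaps of 50–1000 bp so some genes deliberately fail the
isolation filters, and 10% of sn/snoRNAs relocated into mRNA hosts to
exercise the class-overlap filter. These sizes keep the full pipeline
under a minute on one CPU while leaving ≥ 29 sn/snoRNAs in every filtered
set.

- **ChIP**: input fragments uniform; IP fragment midpoints drawn
  proportional to background 1 plus the planted shape — a flat 2×
  multiplier over sn/snoRNA bodies (APT-like) or a σ = 50 bp Gaussian at
  mRNA pA sites (CPF-like); fragment lengths Normal(200, 30) truncated at
  50 bp; mean coverage 5× per library, two replicates.
- **PAR-CLIP**: a quarter of gene-body positions carry a T; coverage is
  Poisson(20 × expression) with lognormal(0, 0.5) per-gene expression;
  three planted sites per gene draw transitions at probability 0.5, all
  other T positions — and all non-transition mismatches — at the 0.005
  error rate; the Pol II track is expression × depth.
- **4tU**: NB counts (dispersion 0.05, 2 vs 2 replicates, library size
  factors 1.0/1.2/0.8/1.1) with baseline means log-uniform on [20, 2000].
  The knockout effect is a class-wide 3-fold sn/snoRNA reduction — the
  phenotype being modeled is a global loss of sn/snoRNA synthesis, and a
  class-wide planting is also the only design under which the *median*
  class shift measures the planted effect rather than a mixture quantile —
  plus 2% of mRNAs down and 5% up (2-fold) so the enrichment test has a
  non-trivial background.

Because fragments are ~200 bp, coverage is the planted intensity convolved
with the fragment-length kernel; genes comparable in length to a fragment
never reach the full multiplier in *body-mean* coverage. The pipeline's
recovery metric therefore counts fragment midpoints per gene (IP vs input,
total-count normalized), which is blur-free and recovers the planted
multiplier without bias; the input denominator is estimated over the gene
±1 kb, which is unbiased for structure-free input and stabilizes the
estimate for short genes. The percent-occupancy statistics and their
Mann–Whitney comparison are still computed on the quantile-anchored
occupancy track, as in the real analysis.

What passing these simulations does **not** show: robustness to
mappability artifacts, GC bias, copy-number structure in the input,
position-specific error rates or SNP clusters in PAR-CLIP, splicing, or
transcriptional interference between neighbouring genes — none of which
the generator models.

## Numerical and design choices

- One seeded `numpy` generator per dataset; every pipeline seed derives
  from the single config seed, and reruns are byte-identical (JSON
  summaries are written with sorted keys and fixed rounding).
- Quantiles are type-7 everywhere (98% gene statistic, 10%/99.8% anchors).
- SES degenerate cases raise (`no signal` for an all-zero track,
  degenerate cut when cumulative input is zero at the max-diff rank)
  rather than returning a non-finite factor.
- The exact binomial tail is used for all site p-values (no normal
  approximation); tests verify agreement with rational-arithmetic
  enumeration to 1e-12 for n ≤ 12.
- Empty inputs: empty annotation files load to empty sets; empty fragment
  lists give zero tracks; an empty profile list or value set raises.

## Known limitations

- The dispersion trend a0 + a1/µ is an unweighted least-squares fit; with
  very few genes (< 2 usable) it degenerates to the mean moment estimate.
- The SES factor on sampled windows inherits the sampling noise of 10⁵
  draws; the full-enumeration mode exists for exactness at toy scale.
- Union-mode counting discards fragments spanning two genes, which
  under-counts genuinely bookended gene pairs; such pairs are excluded by
  the isolation filter in the analysis sets anyway.
- The CLI is a thin convenience layer; multi-sample orchestration beyond
  the synthetic preset is expected to go through the library API.
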