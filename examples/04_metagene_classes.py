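"""Length-scaled metagene profiles and a class comparison.

Builds an occupancy-like track with a planted 3'-end peak on mRNAs, scales
every gene body onto 100 bins (TSS at bin 1, pA at bin 100), averages
within classes, min-max scales the two class profiles jointly, and tests
the per-gene statistics with the two-sided Mann-Whitney U test.
"""

import numpy as np

from polterm.metagene import (
    compare_classes,
    gene_occupancy,
    length_scale_profile,
    metagene_average,
    minmax_scale_classes,
    summarize_boxplot,
)
from polterm.simulate import SimulationConfig, simulate_annotation
from polterm.tracks import CoverageTrack

cfg = SimulationConfig(n_chrom=1, chrom_length=300_000, n_mrna=60, n_snsno=12)
ts, truth = simulate_annotation(cfg, seed=31)

# toy signal: flat 1.0 background, Gaussian bump at every mRNA pA site
track = CoverageTrack({c: np.ones(n) for c, n in ts.genome_lengths.items()})
for t in ts.by_class("mRNA"):
    x = np.arange(ts.genome_lengths[t.chrom])
    track.values[t.chrom] += 2.0 * np.exp(-0.5 * ((x - t.pa_site) / 50) ** 2)

profiles = {
    cls: metagene_average(
        [length_scale_profile(track, t, body_bins=100, flank=200) for t in ts.by_class(cls)]
    )
    for cls in ("mRNA", "snsnoRNA")
}
m, s = minmax_scale_classes(profiles["mRNA"], profiles["snsnoRNA"])
print(f"mRNA profile peaks at body bin {int(np.argmax(m.body_bins)) + 1}/100 "
      f"(scaled height {m.body_bins.max():.2f}) -> the planted pA-site peak")
print(f"sn/snoRNA profile is flat (scaled max {s.body_bins.max():.2f})")

stats = {cls: [gene_occupancy(track, t, 0.98, 100).value for t in ts.by_class(cls)]
         for cls in ("mRNA", "snsnoRNA")}
u, p = compare_classes(stats["mRNA"], stats["snsnoRNA"])
print(f"Mann-Whitney U = {u:.0f}, two-sided p = {p:.3g}")
q1, med, q3, lo, hi = summarize_boxplot(stats["mRNA"])
print(f"mRNA boxplot: Q1={q1:.2f} median={med:.2f} Q3={q3:.2f} whiskers [{lo:.2f}, {hi:.2f}]")
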