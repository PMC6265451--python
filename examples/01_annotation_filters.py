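"""Isolation and class-overlap filtering of a transcript annotation.

Builds a small annotation with a crowded gene pair and a snoRNA nested in
an mRNA, then applies the two filters that define the analysis gene sets:
a minimum intergenic gap (150 nt same-strand for RNA-side analyses, 200 bp
both-strand for ChIP) and removal of overlapping mRNA/sn-snoRNA loci.
"""

from polterm.annotations import (
    Transcript,
    TranscriptSet,
    exclude_overlapping_classes,
    filter_isolated,
)

ts = TranscriptSet(
    [
        Transcript("mRNA_1", "chrI", "+", 0, 1500, "mRNA"),
        Transcript("mRNA_2", "chrI", "+", 1600, 3000, "mRNA"),   # only 100 bp away
        Transcript("mRNA_3", "chrI", "-", 4000, 5500, "mRNA"),
        Transcript("snoRNA_1", "chrI", "+", 4500, 4800, "snsnoRNA"),  # inside mRNA_3
        Transcript("snoRNA_2", "chrI", "+", 7000, 7300, "snsnoRNA"),
    ],
    {"chrI": 10_000},
)

iso = filter_isolated(ts, min_gap=150, strand_mode="same")
print(f"isolation filter (>=150 nt, same strand): kept {[t.id for t in iso]}")
# mRNA_1/mRNA_2 are 100 bp apart, so both fail

clean = exclude_overlapping_classes(iso)
print(f"class-overlap filter: kept {[t.id for t in clean]}")
# snoRNA_1 overlaps mRNA_3 (opposite strands still count), so both drop;
# the surviving set is what every downstream class comparison uses
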