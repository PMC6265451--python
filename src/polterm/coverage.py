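"""Paired-end fragments and physical coverage.

Physical coverage counts, at every genomic position, the number of sequenced
DNA *fragments* spanning it — including the unsequenced insert between the
two mates of a proper pair.  This is the natural occupancy readout for
crosslinked-chromatin fragments, where the protein may sit anywhere on the
fragment, not only under the sequenced ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

from .tracks import CoverageTrack

__all__ = ["Fragment", "read_fragments", "physical_coverage", "median_fragment_size", "write_sam"]

log = logging.getLogger(__name__)

# proper-pair primary-alignment flag values for FR paired-end data
_PROPER_FLAGS = {99, 147, 83, 163}


@dataclass(frozen=True)
class Fragment:
    """Span from the leftmost aligned base of a read pair to the rightmost."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("fragment start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_fragments(
    path, mapq_min: int = 7, proper_pairs_only: bool = True
) -> tuple[list[Fragment], dict[str, int]]:
    """Read a SAM file into fragments, one per retained proper pair.

    Both mates must reach ``mapq_min``; unmapped, secondary and
    supplementary alignments are dropped, as are pairs outside the
    FR proper-pair flag set when ``proper_pairs_only``.  Orphaned mates
    left over after filtering are dropped with a logged count.

    Returns the fragments and the genome lengths from the SAM header.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    frags: list[Fragment] = []
    n_orphan = 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        genome_lengths = dict(zip(sam.references, sam.lengths))
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if proper_pairs_only and read.flag not in _PROPER_FLAGS:
                continue
            if read.mapping_quality < mapq_min:
                # the pair is void even if the mate passes
                pending.pop(read.query_name, None)
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            if mate.reference_name != read.reference_name:
                n_orphan += 1
                continue
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            frags.append(Fragment(read.reference_name, start, end))
    n_orphan += len(pending)
    if n_orphan:
        log.info("read_fragments: dropped %d orphaned/unpaired mates", n_orphan)
    return frags, genome_lengths


def physical_coverage(frags: list[Fragment], genome_lengths: dict[str, int]) -> CoverageTrack:
    """Per-base count of fragments whose [start, end) contains the position."""
    diffs = {c: np.zeros(n + 1, dtype=float) for c, n in genome_lengths.items()}
    for f in frags:
        if f.chrom not in diffs:
            raise ValueError(f"fragment on unknown chromosome {f.chrom!r}")
        if f.start < 0 or f.end > genome_lengths[f.chrom]:
            raise ValueError(
                f"fragment {f.chrom}:{f.start}-{f.end} outside chromosome bounds"
            )
        diffs[f.chrom][f.start] += 1
        diffs[f.chrom][f.end] -= 1
    return CoverageTrack({c: np.cumsum(d[:-1]) for c, d in diffs.items()})


def median_fragment_size(frags: list[Fragment]) -> float:
    """Median fragment length; the SES fragment-size parameter."""
    if not frags:
        raise ValueError("no fragments")
    return float(np.median([f.length for f in frags]))


def write_sam(
    frags: list[Fragment], genome_lengths: dict[str, int], path, read_len: int = 50
) -> None:
    """Write fragments as a minimal valid SAM of FR proper pairs.

    Each fragment becomes one pair: mate 1 on the forward strand at the
    fragment start, mate 2 reverse at the end.  Fragments shorter than
    ``read_len`` get fully overlapping mates.
    """
    header = pysam.AlignmentHeader.from_references(
        list(genome_lengths), [genome_lengths[c] for c in genome_lengths]
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, f in enumerate(frags):
            rl = min(read_len, f.length)
            tid = out.get_tid(f.chrom)
            r1 = pysam.AlignedSegment(header)
            r1.query_name = f"frag{i}"
            r1.reference_id = tid
            r1.reference_start = f.start
            r1.mapping_quality = 60
            r1.cigarstring = f"{rl}M"
            r1.query_sequence = "N" * rl
            r1.flag = 99
            r1.next_reference_id = tid
            r1.next_reference_start = f.end - rl
            r1.template_length = f.length
            r2 = pysam.AlignedSegment(header)
            r2.query_name = f"frag{i}"
            r2.reference_id = tid
            r2.reference_start = f.end - rl
            r2.mapping_quality = 60
            r2.cigarstring = f"{rl}M"
            r2.query_sequence = "N" * rl
            r2.flag = 147
            r2.next_reference_id = tid
            r2.next_reference_start = f.start
            r2.template_length = -f.length
            out.write(r1)
            out.write(r2)
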