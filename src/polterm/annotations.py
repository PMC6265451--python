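"""Transcript annotations: loading, filtering and the analysis gene sets.

Transcript classes are compared throughout the package: protein-coding
mRNAs, sn/snoRNAs (small nuclear and nucleolar non-coding RNAs) and CUTs
(cryptic unstable transcripts).  Two filters define the analyzed gene sets:

* an isolation filter — keep transcripts at least ``min_gap`` bp away from
  any neighboring transcript, either on the same strand (RNA-side analyses,
  150 nt) or on both strands (DNA-side ChIP analyses, 200 bp);
* a class-overlap filter — drop every mRNA/sn-snoRNA pair that overlaps
  (e.g. snoRNAs encoded inside mRNA introns), since class comparisons would
  otherwise double-count the locus.

Coordinates are 0-based half-open internally; GFF3 I/O is 1-based closed and
BED I/O 0-based half-open, per the respective standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Transcript",
    "TranscriptSet",
    "CLASSES",
    "load_annotations",
    "write_bed",
    "filter_isolated",
    "exclude_overlapping_classes",
]

CLASSES = ("mRNA", "snsnoRNA", "CUT")


@dataclass(frozen=True)
class Transcript:
    """A stranded genomic interval with TSS, pA site and class label."""

    id: str
    chrom: str
    strand: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    tclass: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"transcript {self.id}: start must be < end")
        if self.tclass not in CLASSES:
            raise ValueError(f"transcript {self.id}: unknown class {self.tclass!r}")

    @property
    def tss(self) -> int:
        """Transcription start site (5' terminus, 0-based position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def pa_site(self) -> int:
        """Polyadenylation/3'-end site (3' terminus, 0-based position)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Transcript") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class TranscriptSet:
    transcripts: list[Transcript] = field(default_factory=list)
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate transcript ids: {dup[:5]}")
        for t in self.transcripts:
            if self.genome_lengths:
                if t.chrom not in self.genome_lengths:
                    raise ValueError(f"transcript {t.id}: unknown chromosome {t.chrom!r}")
                if t.end > self.genome_lengths[t.chrom]:
                    raise ValueError(f"transcript {t.id}: extends beyond chromosome end")

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def by_class(self, tclass: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.tclass == tclass]

    def subset(self, keep: set[str]) -> "TranscriptSet":
        return TranscriptSet(
            [t for t in self.transcripts if t.id in keep], dict(self.genome_lengths)
        )


def _parse_class(label: str, class_map: dict[str, str] | None) -> str | None:
    if class_map and label in class_map:
        return class_map[label]
    if label in CLASSES:
        return label
    return None


def load_annotations(
    path,
    class_map: dict[str, str] | None = None,
    genome_lengths: dict[str, int] | None = None,
) -> TranscriptSet:
    """Load transcripts from a BED6 or GFF3 file.

    ``class_map`` maps the feature label (GFF3 ``type`` column, or the part
    of the BED name after ``|``) to a transcript class; labels that are
    already a class name need no mapping.  Features with no class mapping
    are skipped.  If ``genome_lengths`` is omitted, chromosome lengths are
    inferred from the furthest annotated end.
    """
    path = Path(path)
    fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(parts) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    chrom, _, ftype, start1, end1, _, strand, _, attrs = parts[:9]
                    start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
                    tid = None
                    for kv in attrs.split(";"):
                        if kv.startswith("ID="):
                            tid = kv[3:]
                    if tid is None:
                        tid = f"{ftype}_{lineno}"
                    label = ftype
                else:
                    if len(parts) < 6:
                        raise ValueError("expected 6 BED columns")
                    chrom, start0, end0, name, _, strand = parts[:6]
                    start, end = int(start0), int(end0)
                    if "|" in name:
                        tid, label = name.rsplit("|", 1)
                    else:
                        tid, label = name, name
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed record at line {lineno}: {exc}") from exc
            tclass = _parse_class(label, class_map)
            if tclass is None:
                continue
            if genome_lengths is not None and chrom not in genome_lengths:
                raise ValueError(f"{path}: unknown chromosome {chrom!r} at line {lineno}")
            transcripts.append(Transcript(tid, chrom, strand, start, end, tclass))
    if genome_lengths is None:
        genome_lengths = {}
        for t in transcripts:
            genome_lengths[t.chrom] = max(genome_lengths.get(t.chrom, 0), t.end)
    return TranscriptSet(transcripts, dict(genome_lengths))


def write_bed(ts: TranscriptSet, path) -> None:
    """Write a transcript set as BED6; the class rides in the name field."""
    with open(path, "w") as fh:
        for t in ts.transcripts:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.id}|{t.tclass}\t0\t{t.strand}\n")


def _gap(a: Transcript, b: Transcript) -> int:
    """Distance between interval boundaries; overlapping pairs have gap 0."""
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    if a.start >= b.end:
        return a.start - b.end
    if b.start >= a.end:
        return b.start - a.end
    return 0


def filter_isolated(ts: TranscriptSet, min_gap: int, strand_mode: str = "both") -> TranscriptSet:
    """Keep transcripts whose nearest neighbor is at least ``min_gap`` bp away.

    ``strand_mode='same'`` restricts neighbors to the transcript's own
    strand; ``'both'`` considers all transcripts.  Distance is measured
    between the annotated interval boundaries (end-exclusive), so a
    bookended pair has gap 0 and overlapping transcripts always fail any
    positive ``min_gap``.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if strand_mode not in ("same", "both"):
        raise ValueError("strand_mode must be 'same' or 'both'")
    keep: list[Transcript] = []
    by_chrom: dict[str, list[Transcript]] = {}
    for t in ts.transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for t in ts.transcripts:
        ok = True
        for other in by_chrom[t.chrom]:
            if other is t:
                continue
            if strand_mode == "same" and other.strand != t.strand:
                continue
            # overlap counts as gap 0, which fails any positive min_gap
            if _gap(t, other) < min_gap:
                ok = False
                break
        if ok:
            keep.append(t)
    return TranscriptSet(keep, dict(ts.genome_lengths))


def exclude_overlapping_classes(ts: TranscriptSet) -> TranscriptSet:
    """Drop every mRNA/sn-snoRNA pair that overlaps on either strand.

    Both members of an overlapping cross-class pair are removed (a snoRNA
    inside an mRNA intron removes the snoRNA *and* the host mRNA).
    Same-class overlaps are untouched.
    """
    mrnas = ts.by_class("mRNA")
    snrnas = ts.by_class("snsnoRNA")
    bad: set[str] = set()
    for m in mrnas:
        for s in snrnas:
            if m.overlaps(s):
                bad.add(m.id)
                bad.add(s.id)
    return TranscriptSet(
        [t for t in ts.transcripts if t.id not in bad], dict(ts.genome_lengths)
    )
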