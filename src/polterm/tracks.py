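"""Per-base genomic signal tracks and bedGraph I/O.

A :class:`CoverageTrack` holds one float array per chromosome.  Strand-aware
signals (PAR-CLIP occupancies) are represented as a pair of tracks, one per
strand; ChIP physical coverage is unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoverageTrack", "smooth", "average_replicates", "read_bedgraph", "write_bedgraph"]


@dataclass
class CoverageTrack:
    """Per-base numeric signal over a genome.

    Parameters
    ----------
    values
        Mapping chromosome name -> 1-D float array of per-base values.
    """

    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    @classmethod
    def zeros(cls, genome_lengths: dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n, dtype=float) for c, n in genome_lengths.items()})

    def copy(self) -> "CoverageTrack":
        return CoverageTrack({c: v.copy() for c, v in self.values.items()})

    def concat(self) -> np.ndarray:
        """All per-base values as a single array (chromosomes in key order)."""
        if not self.values:
            return np.empty(0)
        return np.concatenate([self.values[c] for c in self.values])

    def same_genome(self, other: "CoverageTrack") -> bool:
        return self.genome_lengths == other.genome_lengths

    def map(self, fn) -> "CoverageTrack":
        return CoverageTrack({c: fn(v) for c, v in self.values.items()})


def _smooth_array(a: np.ndarray, half_window: int) -> np.ndarray:
    """Sliding-window mean with window [p-hw, p+hw], truncated at the edges.

    NaNs are treated as missing: they neither contribute to the window sum
    nor to the window length.
    """
    if half_window == 0:
        return a.copy()
    n = len(a)
    if n == 0:
        return a.copy()
    finite = np.isfinite(a)
    filled = np.where(finite, a, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(idx - half_window, 0)
    hi = np.minimum(idx + half_window + 1, n)
    cnt = ccnt[hi] - ccnt[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (csum[hi] - csum[lo]) / cnt
    out[cnt == 0] = np.nan
    return out


def smooth(track: CoverageTrack, half_window: int = 50) -> CoverageTrack:
    """Sliding-window average with half-window ``half_window`` bp.

    The window at position p is [p - half_window, p + half_window]
    intersected with the chromosome (truncated at the ends), so a constant
    track is a fixed point and half_window 0 is the identity.
    """
    if half_window < 0:
        raise ValueError("half_window must be >= 0")
    return track.map(lambda a: _smooth_array(a, half_window))


def average_replicates(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Per-position arithmetic mean of replicate tracks on one genome."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_genome(t):
            raise ValueError("replicate tracks are on different genomes")
    return CoverageTrack(
        {c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.values}
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as 4-column bedGraph with run-length-merged intervals."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            if len(vals) == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_bedgraph(path, genome_lengths: dict[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense track on the given genome."""
    track = CoverageTrack.zeros(genome_lengths)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed bedGraph record at line {lineno}")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in track.values:
                raise ValueError(f"{path}: unknown chromosome {chrom!r} at line {lineno}")
            if e > len(track.values[chrom]):
                raise ValueError(f"{path}: interval beyond chromosome end at line {lineno}")
            track.values[chrom][s:e] = v
    return track
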