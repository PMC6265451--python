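"""Length-scaled metagene profiles and transcript-class statistics.

Genes differ in length, so per-gene signal is aligned at the TSS and the
gene body is linearly rescaled onto a fixed number of bins so that all
pA sites / 3'-ends coincide; flanks are kept in unscaled bp.  Gene-wise
occupancy is summarized by a high quantile (default 98%) of the smoothed
signal over the gene body plus a short downstream window, robust to single
positions yet sensitive to a 3'-end peak.  Classes are compared with the
two-sided Mann-Whitney U test; two-class profile pairs are scaled jointly
onto [0, 1] so their shapes can be overlaid.

Positions flagged as unreliable (NaN in the input track, e.g. floored
expression in PAR-CLIP normalization) are excluded from bin and metagene
averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .annotations import Transcript
from .tracks import CoverageTrack

__all__ = [
    "MetageneProfile",
    "GeneOccupancy",
    "length_scale_profile",
    "metagene_average",
    "gene_occupancy",
    "gene_mean",
    "minmax_scale_classes",
    "compare_classes",
    "summarize_boxplot",
]


@dataclass
class MetageneProfile:
    """Gene-averaged profile: fixed-bin body flanked by unscaled bp."""

    body_bins: np.ndarray  # length B; bin 1 = TSS, bin B = pA
    upstream_flank: np.ndarray
    downstream_flank: np.ndarray
    n_genes: int
    tclass: str | None = None

    def concat(self) -> np.ndarray:
        return np.concatenate([self.upstream_flank, self.body_bins, self.downstream_flank])


@dataclass(frozen=True)
class GeneOccupancy:
    gene_id: str
    value: float
    tclass: str


def _oriented_region(track: CoverageTrack, t: Transcript, up: int, down: int) -> np.ndarray:
    """Per-base values 5'->3' over [TSS - up, pA + down], NaN-padded at chrom edges."""
    vals = track.values[t.chrom]
    n = len(vals)
    if t.strand == "+":
        lo, hi = t.start - up, t.end + down
    else:
        lo, hi = t.start - down, t.end + up
    pad_lo = max(0, -lo)
    pad_hi = max(0, hi - n)
    seg = vals[max(lo, 0):min(hi, n)]
    seg = np.concatenate([np.full(pad_lo, np.nan), seg, np.full(pad_hi, np.nan)])
    return seg[::-1] if t.strand == "-" else seg


def length_scale_profile(
    track: CoverageTrack, t: Transcript, body_bins: int = 100, flank: int = 200
) -> MetageneProfile:
    """One gene's signal, TSS-aligned, body rescaled onto ``body_bins`` bins.

    The bin value is the mean of constituent per-base values (so a constant
    signal is length-invariant); genes shorter than the bin count are
    linearly interpolated onto bin centers.  Minus-strand profiles are
    reversed so the left edge is always 5'.
    """
    if t.chrom not in track.values:
        raise ValueError(f"transcript {t.id}: chromosome {t.chrom!r} not in track")
    if t.length < 2:
        raise ValueError(f"transcript {t.id}: length must be >= 2")
    region = _oriented_region(track, t, flank, flank)
    up = region[:flank]
    body = region[flank:flank + t.length]
    down = region[flank + t.length:]
    L = t.length
    if np.isfinite(body).all():
        # exact area-weighted binning: bin i averages the per-base step
        # function over [i*L/B, (i+1)*L/B), so the body mean is preserved
        csum = np.concatenate([[0.0], np.cumsum(body)])
        edges = np.arange(body_bins + 1) * L / body_bins
        idx = np.minimum(edges.astype(np.int64), L)
        frac = edges - idx
        s = csum[idx] + np.where(idx < L, body[np.minimum(idx, L - 1)], 0.0) * frac
        bins = np.diff(s) * body_bins / L
    else:
        # masked positions present: fall back to per-bin means over the
        # finite positions mapping to each bin
        bin_idx = (np.arange(L) * body_bins) // L
        finite = np.isfinite(body)
        sums = np.bincount(bin_idx[finite], weights=body[finite], minlength=body_bins)
        cnts = np.bincount(bin_idx[finite], minlength=body_bins)
        with np.errstate(invalid="ignore"):
            bins = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return MetageneProfile(bins, up, down, 1, t.tclass)


def metagene_average(profiles: list[MetageneProfile]) -> MetageneProfile:
    """Per-bin mean over genes; NaN (masked) positions are excluded."""
    if not profiles:
        raise ValueError("cannot average an empty profile list")
    B = len(profiles[0].body_bins)
    if any(len(p.body_bins) != B for p in profiles):
        raise ValueError("profiles have mismatched bin layouts")
    with np.errstate(invalid="ignore"):
        body = np.nanmean([p.body_bins for p in profiles], axis=0)
        up = np.nanmean([p.upstream_flank for p in profiles], axis=0)
        down = np.nanmean([p.downstream_flank for p in profiles], axis=0)
    classes = {p.tclass for p in profiles}
    return MetageneProfile(
        body, up, down, sum(p.n_genes for p in profiles),
        classes.pop() if len(classes) == 1 else None,
    )


def gene_occupancy(
    track: CoverageTrack, t: Transcript, q: float = 0.98, downstream: int = 100
) -> GeneOccupancy:
    """q-quantile of per-base signal over the gene body plus ``downstream`` bp.

    The downstream window follows the strand; the region is truncated at
    chromosome ends and masked (NaN) positions are ignored.
    """
    region = _oriented_region(track, t, 0, downstream)
    vals = region[np.isfinite(region)]
    if len(vals) == 0:
        raise ValueError(f"transcript {t.id}: empty region for gene occupancy")
    return GeneOccupancy(t.id, float(np.quantile(vals, q)), t.tclass)


def gene_mean(track: CoverageTrack, t: Transcript, downstream: int = 0) -> float:
    """Mean per-base signal over the gene body plus ``downstream`` bp."""
    region = _oriented_region(track, t, 0, downstream)
    vals = region[np.isfinite(region)]
    if len(vals) == 0:
        raise ValueError(f"transcript {t.id}: empty region")
    return float(np.mean(vals))


def minmax_scale_classes(
    profile_a: MetageneProfile, profile_b: MetageneProfile
) -> tuple[MetageneProfile, MetageneProfile]:
    """Scale two class profiles jointly: joint min -> 0, joint max -> 1."""
    joint = np.concatenate([profile_a.concat(), profile_b.concat()])
    joint = joint[np.isfinite(joint)]
    lo, hi = float(np.min(joint)), float(np.max(joint))
    if hi == lo:
        raise ValueError("cannot min-max scale jointly constant profiles")

    def _scale(p: MetageneProfile) -> MetageneProfile:
        f = lambda v: (v - lo) / (hi - lo)
        return MetageneProfile(f(p.body_bins), f(p.upstream_flank), f(p.downstream_flank), p.n_genes, p.tclass)

    return _scale(profile_a), _scale(profile_b)


def compare_classes(
    values_a, values_b, exact_budget: int = 10_000
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two value lists.

    Uses the exact null distribution when the product of group sizes is
    within ``exact_budget`` and there are no ties across groups; otherwise
    the normal approximation with midrank tie correction.  Returns
    (U statistic for the first group, two-sided p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= exact_budget and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def summarize_boxplot(values) -> tuple[float, float, float, float, float]:
    """(q1, median, q3, whisker_lo, whisker_hi) with Tukey 1.5*IQR whiskers.

    Whiskers sit at the most extreme data points inside the fences.
    """
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty value set")
    q1, med, q3 = (float(np.quantile(v, q)) for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return q1, med, q3, float(np.min(inside)), float(np.max(inside))
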