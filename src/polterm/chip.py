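"""ChIP-seq occupancy: SES normalization, log-ratio enrichment, percent scale.

The IP library is compared against a sonicated-input control.  Because IP
and input libraries differ in depth and signal-to-noise, the input is first
rescaled by a signal-extraction-scaling (SES) factor so that *background*
regions match; enrichment is then log2(IP / scaled input), and enrichment is
mapped onto a 0-100 "percent occupancy" scale anchored at genome-wide
quantiles so that different factors become comparable at the same loci.

SES (Diaz-style): sample many fixed-length windows, sort them by IP signal,
and find the rank where the cumulative-fraction curves of input and IP
diverge the most — everything below that rank is treated as background, and
the factor is the IP/input ratio of the cumulative sums there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import CoverageTrack, smooth  # noqa: F401  (smooth re-exported)

__all__ = ["SESResult", "OccupancyTrack", "ses_scale_factor", "enrichment_track", "to_occupancy", "smooth"]


@dataclass(frozen=True)
class SESResult:
    scale_factor: float  # multiplies the input track
    n_bins: int
    bin_length: int
    max_diff_rank: int  # 1-based rank of the background/signal cut
    seed: int | None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.scale_factor) and self.scale_factor > 0):
            raise ValueError("SES scale factor must be finite and positive")


@dataclass
class OccupancyTrack:
    """Percent-occupancy values in [0, 100] plus the quantile anchors used."""

    track: CoverageTrack
    q_lo_value: float  # log2-ratio mapped to 0%
    q_hi_value: float  # log2-ratio mapped to 100%

    @property
    def values(self) -> dict[str, np.ndarray]:
        return self.track.values


def _window_sums(track: CoverageTrack, bin_length: int):
    """Cumulative arrays per chromosome for O(1) window sums."""
    return {c: np.concatenate([[0.0], np.cumsum(v)]) for c, v in track.values.items()}


def ses_scale_factor(
    ip: CoverageTrack,
    input_: CoverageTrack,
    bin_length: int = 100,
    n_bins: int | None = 100_000,
    seed: int | None = None,
) -> SESResult:
    """SES factor from sampled (or exhaustively tiled) genome windows.

    With ``n_bins`` set, that many windows of ``bin_length`` are drawn at
    seeded random positions with replacement; with ``n_bins=None`` the
    genome is tiled into consecutive non-overlapping windows (deterministic
    full enumeration, used for testing and small genomes).

    Windows are sorted by ascending IP sum; with cumulative fractions
    F_ip(k), F_in(k) over sorted ranks, the cut is the last rank maximizing
    F_in(k) - F_ip(k), and the factor is (cumulative IP) / (cumulative
    input) there.  The factor multiplies the input track.
    """
    if not ip.same_genome(input_):
        raise ValueError("IP and input tracks are on different genomes")
    chroms = [c for c, n in ip.genome_lengths.items() if n >= bin_length]
    if not chroms:
        raise ValueError("genome shorter than bin_length")
    cip = _window_sums(ip, bin_length)
    cin = _window_sums(input_, bin_length)

    if n_bins is None:
        ip_sums, in_sums = [], []
        for c in chroms:
            n_win = ip.genome_lengths[c] // bin_length
            starts = np.arange(n_win) * bin_length
            ip_sums.append(cip[c][starts + bin_length] - cip[c][starts])
            in_sums.append(cin[c][starts + bin_length] - cin[c][starts])
        ip_s = np.concatenate(ip_sums)
        in_s = np.concatenate(in_sums)
        used_bins = len(ip_s)
    else:
        rng = np.random.default_rng(seed)
        lengths = np.array([ip.genome_lengths[c] - bin_length + 1 for c in chroms], dtype=float)
        chrom_idx = rng.choice(len(chroms), size=n_bins, p=lengths / lengths.sum())
        starts = (rng.random(n_bins) * lengths[chrom_idx]).astype(np.int64)
        ip_s = np.empty(n_bins)
        in_s = np.empty(n_bins)
        for i, c in enumerate(chroms):
            m = chrom_idx == i
            ip_s[m] = cip[c][starts[m] + bin_length] - cip[c][starts[m]]
            in_s[m] = cin[c][starts[m] + bin_length] - cin[c][starts[m]]
        used_bins = n_bins

    tot_ip, tot_in = ip_s.sum(), in_s.sum()
    if tot_ip == 0 or tot_in == 0:
        raise ValueError("no signal: IP or input track sums to zero over sampled bins")
    order = np.argsort(ip_s, kind="stable")
    cum_ip = np.cumsum(ip_s[order])
    cum_in = np.cumsum(in_s[order])
    diff = cum_in / tot_in - cum_ip / tot_ip
    # last rank attaining the max: for flat curves (identical shapes) this
    # degenerates to the total-sum ratio
    rank = len(diff) - 1 - int(np.argmax(diff[::-1]))
    if cum_in[rank] == 0:
        raise ValueError("degenerate SES cut: zero cumulative input at max-diff rank")
    factor = float(cum_ip[rank] / cum_in[rank])
    return SESResult(factor, used_bins, bin_length, rank + 1, seed)


def enrichment_track(
    ip: CoverageTrack, input_: CoverageTrack, ses: SESResult, pseudocount: float = 1.0
) -> CoverageTrack:
    """log2((IP + pc) / (scale_factor * input + pc)) per base."""
    if not ip.same_genome(input_):
        raise ValueError("IP and input tracks are on different genomes")
    return CoverageTrack(
        {
            c: np.log2((ip.values[c] + pseudocount) / (ses.scale_factor * input_.values[c] + pseudocount))
            for c in ip.values
        }
    )


def to_occupancy(
    enr: CoverageTrack, q_hi: float = 0.998, q_lo: float = 0.10
) -> OccupancyTrack:
    """Map log2 enrichment linearly onto [0, 100] percent occupancy.

    The genome-wide ``q_lo`` quantile becomes 0% and ``q_hi`` becomes 100%
    (linear interpolation of order statistics); values outside the anchors
    are clamped.
    """
    if not q_lo < q_hi:
        raise ValueError("q_lo must be < q_hi")
    allv = enr.concat()
    a = float(np.quantile(allv, q_lo))
    b = float(np.quantile(allv, q_hi))
    if b == a:
        raise ValueError("degenerate quantiles: q_hi and q_lo anchors coincide")
    scaled = enr.map(lambda v: np.clip(100.0 * (v - a) / (b - a), 0.0, 100.0))
    return OccupancyTrack(scaled, a, b)
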