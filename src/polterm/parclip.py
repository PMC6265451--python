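"""PAR-CLIP crosslink-site calling and expression-normalized RNA occupancy.

4-thiouridine incorporated into nascent RNA crosslinks to bound protein
under UV; reverse transcription through the crosslink leaves a diagnostic
T-to-C transition, so genuine protein-RNA contacts appear as T positions
with an excess of T->C mismatches over the sequencing-error background.

Sites are called against a binomial null: with per-read error probability
``p_err`` (estimated from mismatch types that cannot be crosslink-induced),
the probability of observing at least k transitions among n reads is the
upper binomial tail.  Called sites require p <= 0.005 and coverage >= 2; no
multiplicity adjustment is applied (a deliberately stringent fixed cutoff).

The number of transition reads at a site scales with factor occupancy times
the local RNA concentration, so occupancies are normalized by an expression
track (Pol II PAR-CLIP coverage), smoothed beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import CoverageTrack, smooth

__all__ = [
    "PileupColumn",
    "ErrorModel",
    "CrosslinkSite",
    "read_pileup",
    "write_pileup",
    "estimate_error_rate",
    "crosslink_pvalue",
    "call_sites",
    "sites_to_track",
    "normalize_by_expression",
    "write_sites_bed",
]

_PILEUP_COLS = ["chrom", "pos", "strand", "ref", "coverage", "tc", "other"]


@dataclass(frozen=True)
class PileupColumn:
    """Read support at one (position, strand): coverage and mismatch counts."""

    chrom: str
    pos: int
    strand: str
    ref_base: str
    coverage: int  # n
    tc_count: int  # k, T->C transition reads
    other_mismatch: int

    def __post_init__(self) -> None:
        if not 0 <= self.tc_count <= self.coverage:
            raise ValueError("tc_count must satisfy 0 <= k <= coverage")
        if not 0 <= self.other_mismatch <= self.coverage:
            raise ValueError("other_mismatch out of range")


@dataclass(frozen=True)
class ErrorModel:
    """Single global per-read probability of a spurious transition."""

    p_err: float
    n_positions_used: int

    def __post_init__(self) -> None:
        if not 0 < self.p_err < 1:
            raise ValueError("p_err must be in (0, 1)")


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    pos: int
    strand: str
    k: int
    n: int
    p_value: float
    raw_occupancy: float  # transition read count
    norm_occupancy: float | None = None  # k / expression, filled by normalization


def read_pileup(path) -> list[PileupColumn]:
    """Read a per-position pileup TSV (chrom, pos, strand, ref, coverage, tc, other)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_PILEUP_COLS)
    except pd.errors.EmptyDataError:
        return []
    if len(df) and df.iloc[0]["chrom"] == "chrom":  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    cols = []
    for i, row in enumerate(df.itertuples(index=False), 1):
        try:
            cols.append(
                PileupColumn(
                    str(row.chrom), int(row.pos), str(row.strand), str(row.ref),
                    int(row.coverage), int(row.tc), int(row.other),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: invalid pileup row {i}: {exc}") from exc
    return cols


def write_pileup(cols: list[PileupColumn], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("#" + "\t".join(_PILEUP_COLS) + "\n")
        for c in cols:
            fh.write(
                f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.ref_base}\t{c.coverage}\t{c.tc_count}\t{c.other_mismatch}\n"
            )


def estimate_error_rate(cols: list[PileupColumn], floor: float = 1e-6) -> ErrorModel:
    """Global mismatch rate from non-transition mismatches.

    Non-T->C mismatches cannot be crosslink-induced, so their pooled rate
    estimates the combined sequencing-error / SNP background, floored at
    ``floor`` to keep the binomial null proper when no errors are seen.
    """
    tot_cov = sum(c.coverage for c in cols)
    if tot_cov == 0:
        raise ValueError("cannot estimate error rate: zero total coverage")
    tot_other = sum(c.other_mismatch for c in cols)
    return ErrorModel(max(tot_other / tot_cov, floor), len(cols))


def crosslink_pvalue(k: int, n: int, p_err: float) -> float:
    """Upper-tail binomial probability P(X >= k | n, p_err)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p_err < 1:
        raise ValueError("p_err must be in (0, 1)")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p_err))


def call_sites(
    cols: list[PileupColumn],
    error_model: ErrorModel,
    p_cut: float = 0.005,
    min_cov: int = 2,
) -> list[CrosslinkSite]:
    """Call crosslink sites at sense-strand T positions.

    A site needs reference base T, coverage >= ``min_cov``, at least one
    transition read, and upper-tail binomial p <= ``p_cut``.
    """
    sites = []
    for c in cols:
        if c.ref_base != "T" or c.coverage < min_cov or c.tc_count < 1:
            continue
        p = crosslink_pvalue(c.tc_count, c.coverage, error_model.p_err)
        if p <= p_cut:
            sites.append(
                CrosslinkSite(c.chrom, c.pos, c.strand, c.tc_count, c.coverage, p, float(c.tc_count))
            )
    return sites


def sites_to_track(
    sites: list[CrosslinkSite], genome_lengths: dict[str, int], strand: str
) -> CoverageTrack:
    """Transition-read counts of called sites on one strand as a track."""
    track = CoverageTrack.zeros(genome_lengths)
    for s in sites:
        if s.strand == strand:
            track.values[s.chrom][s.pos] += s.k
    return track


def normalize_by_expression(
    tc_track: CoverageTrack,
    polii: CoverageTrack,
    min_expr: float = 1.0,
    presmooth_half_window: int = 50,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Divide transition-read counts by smoothed expression coverage.

    The expression (Pol II) track is smoothed with the given half-window
    first; positions where it falls below ``min_expr`` are floored at
    ``min_expr`` and flagged in the returned mask so that downstream
    metagene averages can exclude them.

    Returns ``(normalized_track, floored_mask)`` where the mask is 1.0 at
    floored positions.
    """
    if not tc_track.same_genome(polii):
        raise ValueError("tc and expression tracks are on different genomes")
    sm = smooth(polii, presmooth_half_window) if presmooth_half_window > 0 else polii
    norm = {}
    mask = {}
    for c in tc_track.values:
        expr = sm.values[c]
        floored = expr < min_expr
        norm[c] = tc_track.values[c] / np.maximum(expr, min_expr)
        mask[c] = floored.astype(float)
    return CoverageTrack(norm), CoverageTrack(mask)


def write_sites_bed(sites: list[CrosslinkSite], path) -> None:
    """Called sites as BED6 with score = -log10 p (capped at 400)."""
    with open(path, "w") as fh:
        for s in sites:
            score = 400.0 if s.p_value <= 0 else min(-np.log10(s.p_value), 400.0)
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\txl_{s.chrom}_{s.pos}\t{score:.2f}\t{s.strand}\n")
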