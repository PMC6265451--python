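"""Length-scaled profiles, gene statistics and class comparisons."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polterm.annotations import Transcript
from polterm.metagene import (
    MetageneProfile,
    compare_classes,
    gene_occupancy,
    length_scale_profile,
    metagene_average,
    minmax_scale_classes,
    summarize_boxplot,
)
from polterm.tracks import CoverageTrack


def _track(values):
    return CoverageTrack({"chrI": np.asarray(values, dtype=float)})


def mwu_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by full enumeration of group labels."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), 1)}  # no ties assumed
    def u_of(idx):
        ra = sum(ranks[pooled[i]] for i in idx)
        return ra - n_a * (n_a + 1) / 2
    u_obs = u_of(range(n_a))
    us = [u_of(c) for c in combinations(range(len(pooled)), n_a)]
    mean_u = len(a) * len(b) / 2
    dev = abs(u_obs - mean_u)
    p = sum(1 for u in us if abs(u - mean_u) >= dev - 1e-12) / len(us)
    return min(p, 1.0)


class TestLengthScale:
    def test_constant_track(self):
        t = Transcript("g", "chrI", "+", 300, 500, "mRNA")
        prof = length_scale_profile(_track(np.full(1000, 3.0)), t, body_bins=100, flank=200)
        assert np.allclose(prof.body_bins, 3.0)
        assert np.allclose(prof.upstream_flank, 3.0)

    def test_half_on_half_off(self):
        v = np.zeros(1000)
        v[300:400] = 1.0  # first half of a 200 bp gene
        t = Transcript("g", "chrI", "+", 300, 500, "mRNA")
        prof = length_scale_profile(_track(v), t, body_bins=100, flank=0)
        assert np.allclose(prof.body_bins[:50], 1.0)
        assert np.allclose(prof.body_bins[50:], 0.0)

    def test_minus_strand_orientation(self):
        v = np.arange(1000, dtype=float)  # increasing in genomic coords
        t = Transcript("g", "chrI", "-", 300, 500, "mRNA")
        prof = length_scale_profile(_track(v), t, body_bins=50, flank=0)
        assert np.all(np.diff(prof.body_bins) < 0)  # 5'->3' decreasing

    def test_short_gene_interpolated(self):
        v = np.zeros(100)
        v[10:20] = 5.0
        t = Transcript("g", "chrI", "+", 10, 20, "snsnoRNA")
        prof = length_scale_profile(_track(v), t, body_bins=40, flank=0)
        assert np.allclose(prof.body_bins, 5.0)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_body_mean_preserved(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(150, 900))
        v = rng.random(2000)
        t = Transcript("g", "chrI", "+", 500, 500 + L, "mRNA")
        prof = length_scale_profile(_track(v), t, body_bins=100, flank=0)
        body = v[500:500 + L]
        # area-weighted binning preserves the body mean exactly
        assert abs(np.mean(prof.body_bins) - body.mean()) <= 1e-9


class TestMetageneAverage:
    def _prof(self, val, n=10):
        return MetageneProfile(np.full(n, float(val)), np.empty(0), np.empty(0), 1, "mRNA")

    def test_mean_of_two(self):
        avg = metagene_average([self._prof(0), self._prof(2)])
        assert np.allclose(avg.body_bins, 1.0)
        assert avg.n_genes == 2

    def test_single_identity(self):
        avg = metagene_average([self._prof(4)])
        assert np.allclose(avg.body_bins, 4.0)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            metagene_average([])

    def test_nan_excluded(self):
        a = MetageneProfile(np.array([1.0, np.nan]), np.empty(0), np.empty(0), 1, None)
        b = MetageneProfile(np.array([3.0, 5.0]), np.empty(0), np.empty(0), 1, None)
        avg = metagene_average([a, b])
        assert avg.body_bins[0] == 2.0 and avg.body_bins[1] == 5.0


class TestGeneOccupancy:
    def test_constant_region(self):
        t = Transcript("g", "chrI", "+", 100, 300, "mRNA")
        g = gene_occupancy(_track(np.full(1000, 9.0)), t)
        assert g.value == 9.0

    def test_matches_sort_interpolate_oracle(self):
        v = np.zeros(1000)
        v[150] = 10.0
        t = Transcript("g", "chrI", "+", 100, 200, "mRNA")  # region = 100..300 (+100 down)
        g = gene_occupancy(_track(v), t, q=0.98, downstream=100)
        region = np.sort(v[100:300])
        # type-7 linear interpolation oracle
        h = (len(region) - 1) * 0.98
        lo, frac = int(np.floor(h)), h - np.floor(h)
        expect = region[lo] * (1 - frac) + region[min(lo + 1, len(region) - 1)] * frac
        assert g.value == pytest.approx(expect, abs=1e-12)

    def test_q1_is_max(self):
        v = np.zeros(1000)
        v[150] = 10.0
        t = Transcript("g", "chrI", "+", 100, 200, "mRNA")
        assert gene_occupancy(_track(v), t, q=1.0).value == 10.0

    def test_downstream_follows_strand(self):
        v = np.zeros(1000)
        v[95] = 50.0  # 5 bp upstream-of-start on + strand, downstream of a - gene
        t_minus = Transcript("g", "chrI", "-", 100, 200, "mRNA")
        assert gene_occupancy(_track(v), t_minus, q=1.0, downstream=10).value == 50.0
        t_plus = Transcript("g2", "chrI", "+", 100, 200, "mRNA")
        assert gene_occupancy(_track(v), t_plus, q=1.0, downstream=10).value == 0.0


class TestMinMaxScale:
    def _prof(self, vals):
        return MetageneProfile(np.asarray(vals, dtype=float), np.empty(0), np.empty(0), 1, None)

    def test_linear_map(self):
        a, b = minmax_scale_classes(self._prof([2, 4]), self._prof([0, 8]))
        assert np.allclose(a.body_bins, [0.25, 0.5])
        assert np.allclose(b.body_bins, [0.0, 1.0])

    def test_idempotent_on_unit_range(self):
        a, b = minmax_scale_classes(self._prof([0, 0.5]), self._prof([0.2, 1.0]))
        assert np.allclose(a.body_bins, [0, 0.5])
        assert np.allclose(b.body_bins, [0.2, 1.0])

    def test_shift_invariance(self):
        a1, b1 = minmax_scale_classes(self._prof([2, 4]), self._prof([0, 8]))
        a2, b2 = minmax_scale_classes(self._prof([7, 9]), self._prof([5, 13]))
        assert np.allclose(a1.body_bins, a2.body_bins)
        assert np.allclose(b1.body_bins, b2.body_bins)

    def test_constant_error(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_scale_classes(self._prof([1, 1]), self._prof([1, 1]))


class TestCompareClasses:
    def test_separated_triples(self):
        u, p = compare_classes([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups(self):
        _, p = compare_classes([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_separated_quads(self):
        u, p = compare_classes([1, 2, 3, 4], [5, 6, 7, 8])
        assert u == 0
        assert p == pytest.approx(2 / comb(8, 4), abs=1e-12)

    @given(st.integers(0, 5000))
    @settings(max_examples=30, deadline=None)
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 6))
        pooled = rng.permutation(20)[: n_a + n_b]  # distinct values, no ties
        a, b = list(pooled[:n_a]), list(pooled[n_a:])
        _, p = compare_classes(a, b)
        assert p == pytest.approx(mwu_exact_oracle(a, b), abs=1e-9)


class TestBoxplot:
    def test_one_to_five(self):
        assert summarize_boxplot([1, 2, 3, 4, 5]) == (2, 3, 4, 1, 5)

    def test_constant(self):
        assert summarize_boxplot([7, 7, 7]) == (7, 7, 7, 7, 7)

    def test_single_value(self):
        assert summarize_boxplot([3]) == (3, 3, 3, 3, 3)

    def test_outlier_excluded_from_whisker(self):
        vals = [1, 2, 3, 4, 5, 100]
        q1, med, q3, lo, hi = summarize_boxplot(vals)
        assert hi < 100
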