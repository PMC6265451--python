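"""Counting, normalization and the NB differential-synthesis test."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from polterm.annotations import Transcript, TranscriptSet
from polterm.coverage import Fragment
from polterm.diffsynth import (
    KO,
    WT,
    CountMatrix,
    call_de,
    class_enrichment,
    count_reads,
    filter_expressed,
    median_class_shift,
    nb_test,
    size_factors,
)


def fisher_oracle(table):
    """Two-sided Fisher p: sum of hypergeometric point probs <= observed."""
    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    def pt(x):
        return Fraction(comb(r1, x) * comb(n - r1, c1 - x), comb(n, c1))
    p_obs = pt(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return float(sum(pt(x) for x in range(lo, hi + 1) if pt(x) <= p_obs))


def _cm(counts, classes=None, conditions=None):
    df = pd.DataFrame(counts)
    df.index = [f"g{i}" for i in range(len(df))]
    classes = pd.Series(classes or ["mRNA"] * len(df), index=df.index)
    conditions = conditions or [WT] * df.shape[1]
    return CountMatrix(df, classes, conditions)


class TestCountReads:
    GENES = TranscriptSet(
        [
            Transcript("g1", "chrI", "+", 100, 300, "mRNA"),
            Transcript("g2", "chrI", "+", 400, 600, "mRNA"),
            Transcript("g3", "chrI", "-", 700, 900, "snsnoRNA"),
        ],
        {"chrI": 2000},
    )

    def test_inside_one_gene(self):
        c = count_reads([Fragment("chrI", 150, 250, "+")], self.GENES)
        assert c["g1"] == 1 and c["g2"] == 0

    def test_spanning_two_genes_discarded(self):
        c = count_reads([Fragment("chrI", 250, 450, "+")], self.GENES)
        assert c.sum() == 0

    def test_intergenic_discarded(self):
        assert count_reads([Fragment("chrI", 950, 1000, "+")], self.GENES).sum() == 0

    def test_strand_aware(self):
        c = count_reads([Fragment("chrI", 750, 800, "+")], self.GENES)
        assert c["g3"] == 0
        c = count_reads([Fragment("chrI", 750, 800, "-")], self.GENES)
        assert c["g3"] == 1


class TestSizeFactors:
    def test_identical_samples(self):
        cm = _cm({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert np.allclose(size_factors(cm.counts), [1.0, 1.0])

    def test_doubled_sample(self):
        cm = _cm({"s1": [10, 20, 100], "s2": [20, 40, 200]})
        f = size_factors(cm.counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample(self):
        cm = _cm({"s1": [5, 10]})
        assert np.allclose(size_factors(cm.counts), [1.0])

    def test_no_common_gene_error(self):
        cm = _cm({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            size_factors(cm.counts)

    @given(st.floats(0.5, 4.0), st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_scale_consistency(self, c, seed):
        rng = np.random.default_rng(seed)
        base = rng.integers(1, 1000, size=(20, 3))
        f1 = size_factors(pd.DataFrame(base))
        scaled = base.astype(float).copy()
        scaled[:, 1] = np.round(scaled[:, 1] * c)
        if (scaled[:, 1] == 0).any():
            return
        f2 = size_factors(pd.DataFrame(scaled))
        # scaling one sample by c scales its factor relative to the others
        # by ~c (the geometric-mean reference absorbs c**(1/3))
        assert (f2[1] / f2[0]) / (f1[1] / f1[0]) == pytest.approx(c, rel=0.05)


class TestFilterExpressed:
    def _two_cond(self, wt_counts, ko_counts):
        return _cm(
            {"w1": [wt_counts], "w2": [wt_counts], "k1": [ko_counts], "k2": [ko_counts]},
            conditions=[WT, WT, KO, KO],
        )

    @pytest.mark.parametrize(
        "wt,ko,kept", [(35, 2, True), (29, 29, False), (30, 0, True)]
    )
    def test_either_condition_threshold(self, wt, ko, kept):
        cm = self._two_cond(wt, ko)
        out = filter_expressed(cm, np.ones(4), 30.0)
        assert (len(out.counts) == 1) is kept


class TestNBTest:
    def _design(self, n_rep=2):
        return [WT] * n_rep + [KO] * n_rep

    def test_identical_counts_null(self):
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, size=50)
        counts = {f"w{i}": base for i in range(2)} | {f"k{i}": base for i in range(2)}
        cm = _cm(counts, conditions=self._design())
        res = nb_test(cm, np.ones(4))
        assert np.allclose(res["log2fc"], 0.0)
        assert np.all(res["p_value"] > 0.99)

    def test_planted_threefold_recovered(self):
        # 3 vs 3 replicates, alpha=0.05, mu_wt=300, 500 genes
        rng = np.random.default_rng(1)
        alpha, mu_wt = 0.05, 300.0
        lfc = -np.log2(3)
        n = 500
        wt = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_wt), size=(n, 3))
        ko = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu_wt * 2**lfc), size=(n, 3))
        cm = _cm(
            {f"w{i}": wt[:, i] for i in range(3)} | {f"k{i}": ko[:, i] for i in range(3)},
            conditions=self._design(3),
        )
        res = nb_test(cm, np.ones(6))
        assert np.median(res["log2fc"]) == pytest.approx(lfc, abs=0.15)

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(2)
        alpha = 0.05
        mu = np.exp(rng.uniform(np.log(30), np.log(2000), 1000))
        counts = {
            name: rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
            for name in ("w1", "w2", "k1", "k2")
        }
        cm = _cm(counts, conditions=self._design())
        res = nb_test(cm, np.ones(4))
        assert (res["padj"] < 0.1).mean() <= 0.12

    def test_requires_two_replicates(self):
        cm = _cm({"w1": [10], "k1": [10]}, conditions=[WT, KO])
        with pytest.raises(ValueError, match="replicates"):
            nb_test(cm, np.ones(2))


class TestCalls:
    def _res(self, rows):
        df = pd.DataFrame(rows, columns=["tclass", "log2fc", "padj"])
        df["p_value"] = df["padj"] / 2
        df["base_mean"] = 100.0
        df["call"] = "ns"
        df.index = [f"g{i}" for i in range(len(df))]
        return df

    def test_call_rules(self):
        res = call_de(
            self._res(
                [("mRNA", -2.0, 0.01), ("mRNA", -2.0, 0.5), ("mRNA", 0.1, 0.001)]
            )
        )
        assert list(res["call"]) == ["down", "ns", "ns"]

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(3)
        res = self._res(
            [("mRNA", float(l), float(p)) for l, p in zip(rng.normal(0, 2, 100), rng.random(100))]
        )
        n_strict = (call_de(res, 2.0, 0.05)["call"] != "ns").sum()
        n_loose = (call_de(res, 1.5, 0.1)["call"] != "ns").sum()
        assert n_loose >= n_strict


class TestEnrichmentAndShift:
    def _res_from_table(self, sn_down, sn_not, m_down, m_not):
        rows = (
            [("snsnoRNA", -2.0, "down")] * sn_down
            + [("snsnoRNA", 0.0, "ns")] * sn_not
            + [("mRNA", -2.0, "down")] * m_down
            + [("mRNA", 0.0, "ns")] * m_not
        )
        df = pd.DataFrame(rows, columns=["tclass", "log2fc", "call"])
        df.index = [f"g{i}" for i in range(len(df))]
        return df

    @pytest.mark.parametrize(
        "table,expected",
        [
            (((3, 1), (1, 3)), 34 / 70),
            (((10, 90), (10, 90)), 1.0),
            (((5, 0), (0, 5)), 2 / 252),
        ],
    )
    def test_fisher_examples_and_oracle(self, table, expected):
        (a, b), (c, d) = table
        res = self._res_from_table(a, b, c, d)
        _, p = class_enrichment(res, "down")
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(fisher_oracle(table), rel=1e-9)

    def test_shift_identity_and_sign(self):
        res = self._res_from_table(0, 5, 0, 5)
        assert median_class_shift(res) == 1.0
        res2 = self._res_from_table(5, 0, 0, 5)  # sn/snoRNAs reduced
        assert median_class_shift(res2) == pytest.approx(4.0)


class TestBH:
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60), st.floats(0.01, 0.3))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_definition(self, pvals, q):
        p = np.asarray(pvals)
        rej = multipletests(p, alpha=q, method="fdr_bh")[0]
        # direct step-up oracle
        m = len(p)
        order = np.argsort(p)
        k_max = 0
        for i, idx in enumerate(order, 1):
            if p[idx] <= q * i / m:
                k_max = i
        expect = np.zeros(m, dtype=bool)
        expect[order[:k_max]] = True
        assert np.array_equal(rej, expect)
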