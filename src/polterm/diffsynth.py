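"""4tU-seq differential-synthesis analysis.

Metabolic labeling with 4-thiouracil captures newly synthesized RNA, so
per-gene counts measure transcription rather than steady-state levels.
The analysis follows the standard bulk count-based workflow: median-of-
ratios size factors, an expression floor, a per-gene negative-binomial
Wald test of knockout vs wild-type, Benjamini-Hochberg adjustment, and
fold-change/padj call thresholds; transcript-class enrichment among the
calls is assessed with Fisher's exact test.

The NB test is a defined moment-based procedure: per-gene dispersion by
method of moments on normalized counts (within-condition variability),
shrunk 50/50 toward a 1/mean trend fitted across genes, and a Wald
statistic on the unshrunken log2 fold change.  It is intentionally simple
and fully specified here; no equivalence with any particular DE package is
claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotations import TranscriptSet
from .coverage import Fragment

__all__ = [
    "CountMatrix",
    "count_reads",
    "size_factors",
    "filter_expressed",
    "nb_test",
    "call_de",
    "class_enrichment",
    "median_class_shift",
    "read_counts_tsv",
    "write_counts_tsv",
]

WT = "wild_type"
KO = "delta_syc1"


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus class labels and condition design."""

    counts: pd.DataFrame  # index: gene ids; columns: sample names
    classes: pd.Series  # gene id -> tclass
    conditions: list[str] = field(default_factory=list)  # per column

    def __post_init__(self) -> None:
        if len(self.conditions) != self.counts.shape[1]:
            raise ValueError("one condition label per sample column required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.classes = self.classes.reindex(self.counts.index)

    def cols(self, condition: str) -> list[str]:
        return [c for c, lab in zip(self.counts.columns, self.conditions) if lab == condition]


def count_reads(frags: list[Fragment], genes: TranscriptSet) -> pd.Series:
    """Union-mode fragment counting: a fragment counts for a gene iff it
    overlaps exactly one gene interval on its own strand; fragments hitting
    zero or several genes are discarded."""
    counts = pd.Series(0, index=[t.id for t in genes], dtype=int)
    index: dict[tuple[str, str], list] = {}
    for t in genes:
        index.setdefault((t.chrom, t.strand), []).append(t)
    sorted_idx = {}
    for key, ts in index.items():
        ts.sort(key=lambda t: t.start)
        sorted_idx[key] = (
            np.array([t.start for t in ts]),
            np.array([t.end for t in ts]),
            [t.id for t in ts],
        )
    for f in frags:
        entry = sorted_idx.get((f.chrom, f.strand))
        if entry is None:
            continue
        starts, ends, ids = entry
        hits = [i for i in range(len(ids)) if starts[i] < f.end and ends[i] > f.start]
        if len(hits) == 1:
            counts[ids[hits[0]]] += 1
    return counts


def size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean reference.

    Only genes with nonzero counts in every sample enter the median; the
    factors are not rescaled afterwards.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[allpos]
    log_gm = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_gm[:, None], axis=0))
    return factors


def filter_expressed(cm: CountMatrix, factors: np.ndarray, min_avg_norm: float = 30.0) -> CountMatrix:
    """Keep genes with mean normalized count >= threshold in either condition."""
    norm = cm.counts.to_numpy(dtype=float) / factors
    keep = np.zeros(len(cm.counts), dtype=bool)
    for cond in (WT, KO):
        idx = [i for i, lab in enumerate(cm.conditions) if lab == cond]
        if idx:
            keep |= norm[:, idx].mean(axis=1) >= min_avg_norm
    return CountMatrix(cm.counts.loc[keep], cm.classes.loc[keep], list(cm.conditions))


def _fit_dispersion_trend(mu: np.ndarray, alpha_mm: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha = a0 + a1/mu across genes."""
    ok = (mu > 0) & np.isfinite(alpha_mm)
    if ok.sum() < 2:
        return float(np.nanmean(alpha_mm[ok])) if ok.any() else 1e-8, 0.0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha_mm[ok], rcond=None)
    return float(coef[0]), float(coef[1])


def nb_test(cm: CountMatrix, factors: np.ndarray, alpha_floor: float = 1e-8) -> pd.DataFrame:
    """Per-gene NB Wald test of delta_syc1 vs wild_type.

    Normalized counts y_ij = c_ij / s_j.  Condition means mu_wt, mu_ko; the
    gene dispersion is method-of-moments on within-condition variability,
    floored at ``alpha_floor`` and shrunk 50/50 toward the cross-gene trend
    a0 + a1/mu.  log2FC = log2((mu_ko + c0)/(mu_wt + c0)) with pseudocount
    c0 = 0.5 * mean(s); its standard error follows from the NB variance
    mu + alpha*mu^2 via the delta method, and the Wald p is two-sided
    normal.  BH adjustment runs over all tested genes.
    """
    wt_idx = [i for i, lab in enumerate(cm.conditions) if lab == WT]
    ko_idx = [i for i, lab in enumerate(cm.conditions) if lab == KO]
    if len(wt_idx) < 2 or len(ko_idx) < 2:
        raise ValueError("need >= 2 replicates per condition for dispersion estimation")
    mat = cm.counts.to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0
    if not nonzero.all():
        import warnings

        warnings.warn(f"excluding {int((~nonzero).sum())} all-zero genes from testing")
    mat = mat[nonzero]
    genes = cm.counts.index[nonzero]
    y = mat / factors
    y_wt, y_ko = y[:, wt_idx], y[:, ko_idx]
    mu_wt = y_wt.mean(axis=1)
    mu_ko = y_ko.mean(axis=1)
    mu = y.mean(axis=1)

    # pooled within-condition variance (removes the condition effect)
    n_wt, n_ko = len(wt_idx), len(ko_idx)
    ss = ((y_wt - mu_wt[:, None]) ** 2).sum(axis=1) + ((y_ko - mu_ko[:, None]) ** 2).sum(axis=1)
    var_within = ss / (n_wt + n_ko - 2)
    shot = mu * np.mean(1.0 / factors)  # Poisson part of Var(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mm = np.where(mu > 0, (var_within - shot) / mu**2, alpha_floor)
    alpha_mm = np.maximum(alpha_mm, alpha_floor)
    a0, a1 = _fit_dispersion_trend(mu, alpha_mm)
    with np.errstate(divide="ignore"):
        alpha_tr = np.maximum(a0 + a1 / np.maximum(mu, 1e-12), alpha_floor)
    alpha = 0.5 * alpha_mm + 0.5 * alpha_tr

    c0 = 0.5 * float(np.mean(factors))
    log2fc = np.log2((mu_ko + c0) / (mu_wt + c0))

    inv_s = 1.0 / factors
    var_muhat_wt = (mu_wt[:, None] * inv_s[wt_idx] + alpha[:, None] * mu_wt[:, None] ** 2).sum(axis=1) / n_wt**2
    var_muhat_ko = (mu_ko[:, None] * inv_s[ko_idx] + alpha[:, None] * mu_ko[:, None] ** 2).sum(axis=1) / n_ko**2
    se = np.sqrt(var_muhat_wt / (mu_wt + c0) ** 2 + var_muhat_ko / (mu_ko + c0) ** 2) / np.log(2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.clip(pvals, 0.0, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": genes,
            "tclass": cm.classes.loc[genes].to_numpy(),
            "base_mean": mu,
            "log2fc": log2fc,
            "p_value": pvals,
            "padj": padj,
            "call": "ns",
        }
    ).set_index("gene")


def call_de(results: pd.DataFrame, fc_cut: float = 1.5, padj_cut: float = 0.1) -> pd.DataFrame:
    """Annotate up/down/ns calls from fold-change and padj thresholds."""
    res = results.copy()
    fc = 2.0 ** res["log2fc"]
    sig = res["padj"] < padj_cut
    res["call"] = "ns"
    res.loc[sig & (fc < 1.0 / fc_cut), "call"] = "down"
    res.loc[sig & (fc > fc_cut), "call"] = "up"
    return res


def class_enrichment(results: pd.DataFrame, direction: str = "down") -> tuple[float, float]:
    """Fisher's exact test (two-sided) for sn/snoRNA enrichment among calls.

    2x2 table: rows class in {snsnoRNA, mRNA}, columns call == direction
    vs not.  Returns (odds_ratio, p).
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    sub = results[results["tclass"].isin(["snsnoRNA", "mRNA"])]
    if sub["tclass"].nunique() < 2:
        raise ValueError("both transcript classes must be present")
    is_sn = sub["tclass"] == "snsnoRNA"
    is_dir = sub["call"] == direction
    table = [
        [int((is_sn & is_dir).sum()), int((is_sn & ~is_dir).sum())],
        [int((~is_sn & is_dir).sum()), int((~is_sn & ~is_dir).sum())],
    ]
    if min(sum(table[0]), sum(table[1]), table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
        return 1.0, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def median_class_shift(results: pd.DataFrame) -> float:
    """Fold by which sn/snoRNAs are reduced relative to mRNAs.

    2^(median mRNA log2FC - median sn/snoRNA log2FC); > 1 when sn/snoRNAs
    are more strongly down-regulated.
    """
    m = results.loc[results["tclass"] == "mRNA", "log2fc"]
    s = results.loc[results["tclass"] == "snsnoRNA", "log2fc"]
    if len(m) == 0 or len(s) == 0:
        raise ValueError("both transcript classes must be present")
    return float(2.0 ** (np.median(m) - np.median(s)))


def write_counts_tsv(cm: CountMatrix, path) -> None:
    """Counts TSV with header sample:condition:replicate and a class column."""
    reps: dict[str, int] = {}
    cols = []
    for name, cond in zip(cm.counts.columns, cm.conditions):
        reps[cond] = reps.get(cond, 0) + 1
        cols.append(f"{name}:{cond}:{reps[cond]}")
    out = cm.counts.copy()
    out.columns = cols
    out.insert(0, "tclass", cm.classes)
    out.to_csv(path, sep="\t", index_label="gene")


def read_counts_tsv(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    classes = df.pop("tclass")
    conditions = [c.split(":")[1] for c in df.columns]
    df.columns = [c.split(":")[0] for c in df.columns]
    return CountMatrix(df.astype(int), classes, conditions)
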