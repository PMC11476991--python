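"""Differential-expression calls and hypergeometric term enrichment.

The significance gate for light-responsive genes is |log2 fold change| >= 1
together with FDR < 0.001.  The per-gene (log2fc, fdr) statistics are an
input — typically produced by DESeq2 — but a self-contained stand-in
statistic generator (Welch t-test on log2(FPKM + 1) with Benjamini-Hochberg
adjustment) is provided for synthetic pipelines; it is not a DESeq2
reimplementation.

Term enrichment uses the hypergeometric upper tail P(X >= k) for a query
set of size n against a term annotating K of N universe genes, with raw
p < 0.05 as the significance rule and BH-adjusted p-values reported
alongside.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "call_degs",
    "welch_deg_stats",
    "moderated_deg_stats",
    "hypergeometric_enrichment",
]


def call_degs(
    stats_table: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.001,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify genes as up / down / ns from (gene, log2fc, fdr) statistics.

    up:   log2fc >= lfc_threshold  and fdr < fdr_threshold
    down: log2fc <= -lfc_threshold and fdr < fdr_threshold
    ns:   otherwise.  The fold-change bound is inclusive, the FDR bound
    strict.  Returns the table with a ``call`` column plus count totals.
    """
    required = {"gene", "log2fc", "fdr"}
    if not required.issubset(stats_table.columns):
        raise ValueError(f"stats table must have columns {sorted(required)}")
    if stats_table["fdr"].isna().any():
        bad = stats_table.loc[stats_table["fdr"].isna(), "gene"].tolist()[:5]
        raise ValueError(f"missing FDR for genes {bad}")
    if ((stats_table["fdr"] < 0) | (stats_table["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")

    out = stats_table.copy()
    sig = out["fdr"] < fdr_threshold
    up = sig & (out["log2fc"] >= lfc_threshold)
    down = sig & (out["log2fc"] <= -lfc_threshold)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    counts = {
        "n_up": int(up.sum()),
        "n_down": int(down.sum()),
        "n_total": int(up.sum() + down.sum()),
    }
    return out, counts


def welch_deg_stats(
    fpkm: pd.DataFrame,
    sample_condition: Mapping[str, str],
    condition_pair: tuple[str, str] = ("light", "dark"),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Stand-in per-gene statistics: Welch t-test on log2(FPKM + pseudocount).

    Returns a (gene, log2fc, pvalue, fdr) frame where log2fc is
    condition_pair[0] minus condition_pair[1] on the log2(FPKM + pc) scale
    and fdr is the BH-adjusted p-value.  This is a simple labelled
    substitute for a count-model fit, adequate for synthetic data with
    planted effects.
    """
    num, den = condition_pair
    cols_a = [s for s in fpkm.columns if sample_condition[s] == num]
    cols_b = [s for s in fpkm.columns if sample_condition[s] == den]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    la = np.log2(fpkm[cols_a].to_numpy(dtype=float) + pseudocount)
    lb = np.log2(fpkm[cols_b].to_numpy(dtype=float) + pseudocount)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance degenerate rows
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene": fpkm.index,
            "log2fc": la.mean(axis=1) - lb.mean(axis=1),
            "pvalue": p,
            "fdr": fdr,
        }
    ).reset_index(drop=True)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); returns inf for y ~ 0."""
    from scipy.optimize import brentq
    from scipy.special import polygamma

    if y <= 1e-8:
        return float("inf")
    return float(brentq(lambda x: polygamma(1, x) - y, 1e-8, 1e8, xtol=1e-10))


def moderated_deg_stats(
    fpkm: pd.DataFrame,
    sample_condition: Mapping[str, str],
    condition_pair: tuple[str, str] = ("light", "dark"),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Stand-in per-gene statistics with empirical-Bayes variance moderation.

    A pooled two-sample t-test on log2(FPKM + pc) whose per-gene variance is
    shrunk toward a common prior estimated from all genes (the standard
    small-replicate moderation of limma): the prior df d0 and scale s0^2
    are fitted by matching the moments of log s_g^2 to a scaled F
    distribution, the posterior variance is
    (d0 * s0^2 + d * s_g^2) / (d0 + d), and the moderated t has d + d0
    degrees of freedom.  With few replicates this recovers planted effects
    that a plain per-gene t-test cannot, which is why it is the pipeline
    default; it remains a labelled substitute for a count-model fit, not a
    DESeq2 reimplementation.
    """
    from scipy.special import digamma, polygamma

    num, den = condition_pair
    cols_a = [s for s in fpkm.columns if sample_condition[s] == num]
    cols_b = [s for s in fpkm.columns if sample_condition[s] == den]
    n1, n2 = len(cols_a), len(cols_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    la = np.log2(fpkm[cols_a].to_numpy(dtype=float) + pseudocount)
    lb = np.log2(fpkm[cols_b].to_numpy(dtype=float) + pseudocount)
    lfc = la.mean(axis=1) - lb.mean(axis=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * la.var(axis=1, ddof=1) + (n2 - 1) * lb.var(axis=1, ddof=1)) / d

    # fit the scaled inv-chi2 prior on log s^2 (Fisher's z moments)
    pos = s2[s2 > 0]
    if len(pos) < 2:
        raise ValueError("cannot moderate variances: all genes degenerate")
    e = np.log(pos) - digamma(d / 2.0) + np.log(d / 2.0)
    var_e = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if var_e > 0:
        d0 = 2.0 * _trigamma_inverse(var_e)
        s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    else:  # no excess variability between genes: common variance, z-like test
        s0_sq = float(np.exp(e.mean()))
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
        d0 = float("inf")
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.where(np.isnan(p), 1.0, p), 0.0, 1.0)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {
            "gene": fpkm.index,
            "log2fc": lfc,
            "pvalue": p,
            "fdr": fdr,
        }
    ).reset_index(drop=True)


def hypergeometric_enrichment(
    query_set: set[str] | Sequence[str],
    term_annotation: Mapping[str, set[str]],
    universe: set[str] | Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation test per term.

    For a term annotating K of the N universe genes, with k of the n query
    genes annotated, the p-value is P(X >= k) for
    X ~ Hypergeometric(N, K, n).  A term with K = 0 (or k = 0) has p = 1.
    Significance follows the raw p < alpha rule; BH-adjusted p-values are
    reported alongside for stricter use.

    ``term_annotation`` maps term -> set of annotated genes.  Query genes
    outside the universe are an error (all offenders listed).
    """
    universe = set(universe)
    query = set(query_set)
    outside = sorted(query - universe)
    if outside:
        raise ValueError(f"query genes not in universe: {outside}")
    n, N = len(query), len(universe)
    rows = []
    for term in sorted(term_annotation):
        annotated = set(term_annotation[term]) & universe
        K = len(annotated)
        k = len(annotated & query)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term": term, "k": k, "n": n, "K": K, "N": N, "pvalue": min(p, 1.0)}
        )
    result = pd.DataFrame(rows)
    if len(result):
        _, adj, _, _ = multipletests(result["pvalue"], method="fdr_bh")
        result["adjusted_pvalue"] = np.maximum(adj, result["pvalue"])
        result["significant"] = result["pvalue"] < alpha
        result = result.sort_values(
            ["pvalue", "term"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["adjusted_pvalue"] = []
        result["significant"] = []
    return result
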