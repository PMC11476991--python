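"""FPKM computation, expression-level classification and expressed-gene calls.

Counts are gene x sample matrices of unique-mapped read counts.  FPKM
(fragments per kilobase of transcript per million mapped reads) is

    fpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * library_size[s])

Replicates are summarised per condition by the geometric mean (a zero in
any replicate propagates to a zero mean), genes are binned into the four
half-open expression categories [0,1), [1,10), [10,100), [100,inf), and a
gene is called expressed in a condition when its mean FPKM >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSummary",
    "count_filter",
    "compute_fpkm",
    "condition_means",
    "classify_and_call",
    "replicate_summary",
    "round_half_up",
]

#: ordered expression-category labels for the half-open FPKM bins
CATEGORY_LABELS = ("FPKM<1", "1<=FPKM<10", "10<=FPKM<100", "FPKM>=100")
_CATEGORY_EDGES = (1.0, 10.0, 100.0)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching reported-table precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def count_filter(
    counts: pd.DataFrame, min_reads: int = 5
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop genes with fewer than ``min_reads`` counts in every sample.

    A gene survives if at least one sample reaches the threshold.  Returns
    the filtered matrix and kept/dropped counts.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (counts >= min_reads).any(axis=1)
    filtered = counts.loc[keep]
    return filtered, {"n_kept": int(keep.sum()), "n_dropped": int((~keep).sum())}


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | Mapping[str, float],
    library_sizes: pd.Series | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Elementwise FPKM; library sizes default to per-sample column sums."""
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    fpkm = counts.astype(float).mul(1e9).div(lengths, axis=0).div(lib, axis=1)
    return fpkm


def condition_means(
    fpkm: pd.DataFrame, sample_condition: Mapping[str, str]
) -> pd.DataFrame:
    """Geometric mean of replicate FPKMs per condition.

    If any replicate of a gene is zero the geometric mean is zero (no
    pseudocount).  Returns a gene x condition frame.
    """
    cond = pd.Series({s: sample_condition[s] for s in fpkm.columns})
    out = {}
    for c in sorted(cond.unique()):
        block = fpkm.loc[:, cond.index[cond == c]].to_numpy(dtype=float)
        has_zero = (block <= 0).any(axis=1)
        with np.errstate(divide="ignore"):
            gm = np.exp(np.log(np.where(block > 0, block, 1.0)).mean(axis=1))
        gm[has_zero] = 0.0
        out[c] = gm
    return pd.DataFrame(out, index=fpkm.index)


def categorize(mean_fpkm: pd.DataFrame) -> pd.DataFrame:
    """Assign each finite mean FPKM to exactly one half-open category bin."""
    vals = mean_fpkm.to_numpy(dtype=float)
    idx = np.digitize(vals, _CATEGORY_EDGES, right=False)
    labels = np.asarray(CATEGORY_LABELS, dtype=object)
    return pd.DataFrame(labels[idx], index=mean_fpkm.index, columns=mean_fpkm.columns)


@dataclass
class ConditionSummary:
    """Per-condition expression summary plus the two-condition Venn partition."""

    mean_fpkm: pd.DataFrame
    category: pd.DataFrame
    expressed: pd.DataFrame
    venn: dict[str, int]

    @property
    def n_expressed_total(self) -> int:
        return self.venn["only_a"] + self.venn["only_b"] + self.venn["both"]


def classify_and_call(
    mean_fpkm: pd.DataFrame,
    conditions: Sequence[str] | None = None,
    expressed_threshold: float = 1.0,
) -> ConditionSummary:
    """Categorise expression levels and call expressed genes per condition.

    A gene is expressed in a condition when mean FPKM >= 1; the Venn
    partition over the two conditions (only-A, only-B, both) covers exactly
    the genes expressed in at least one of them.
    """
    if conditions is None:
        conditions = list(mean_fpkm.columns)
    if len(conditions) != 2:
        raise ValueError("Venn partition requires exactly two condition labels")
    a, b = conditions
    category = categorize(mean_fpkm)
    expressed = mean_fpkm >= expressed_threshold
    in_a = set(mean_fpkm.index[expressed[a]])
    in_b = set(mean_fpkm.index[expressed[b]])
    venn = {
        "only_a": len(in_a - in_b),
        "only_b": len(in_b - in_a),
        "both": len(in_a & in_b),
    }
    return ConditionSummary(
        mean_fpkm=mean_fpkm, category=category, expressed=expressed, venn=venn
    )


def replicate_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean and dispersion of a replicate/sample scalar table.

    Means are rounded half-up to two decimals (reporting convention).  The
    dispersion is given as both the sample (ddof=1) and population (ddof=0)
    standard deviation, since summary tables in the literature are
    inconsistent about which is printed.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to summarise replicates")
    for col in table.columns:
        vals = pd.to_numeric(table[col], errors="coerce")
        if vals.isna().any():
            row = table.index[vals.isna()][0]
            raise ValueError(f"non-numeric value in column {col!r}, row {row!r}")
    num = table.astype(float)
    return pd.DataFrame(
        {
            "mean": [round_half_up(m, 2) for m in num.mean()],
            "sd_sample": [round_half_up(s, 2) for s in num.std(ddof=1)],
            "sd_population": [round_half_up(s, 2) for s in num.std(ddof=0)],
        },
        index=num.columns,
    )
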