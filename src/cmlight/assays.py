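"""Wet-lab quantification formulas and light/dark condition comparisons.

Fungal biomass in solid-substrate culture is estimated indirectly from the
glucosamine released by cell-wall chitin hydrolysis:

    glucosamine [mg/gDW] = (C * V_f * V_e) / (W_e * V_a * 1000)
    biomass     [g/kg]   = G * W_f / W_s

with C the standard-curve concentration in ug/mL, V_f/V_e/V_a the final,
extraction-reagent and analysis volumes in mL, W_e the extracted dry
weight in g, G the glucosamine content in mg/gDW, W_f the fermented-sample
dry weight and W_s the substrate dry weight.  The 1000 converts ug to mg.

Metabolite levels (cordycepin, carotenoids) under light vs dark are
compared with a two-sample Student's t-test and reported as
mean +/- sd with the light/dark ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GlucosamineAssay",
    "BiomassInput",
    "ConditionComparison",
    "glucosamine_content",
    "biomass_estimate",
    "compare_conditions",
    "summarize_assays",
]


@dataclass(frozen=True)
class GlucosamineAssay:
    C: float  # ug/mL from the standard curve
    V_f: float  # mL final extraction volume
    V_e: float  # mL extraction reagent volume
    V_a: float  # mL analysis solution volume
    W_e: float  # gDW extracted sample weight

    def __post_init__(self) -> None:
        for name in ("V_f", "V_e", "V_a", "W_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.C < 0:
            raise ValueError("C must be non-negative")


@dataclass(frozen=True)
class BiomassInput:
    G: float  # mg/gDW glucosamine content
    W_f: float  # gDW fermented sample dry weight
    W_s: float  # g substrate dry weight

    def __post_init__(self) -> None:
        if self.W_s <= 0:
            raise ValueError("W_s must be positive")


@dataclass(frozen=True)
class ConditionComparison:
    mean_light: float
    mean_dark: float
    sd_light: float
    sd_dark: float
    n_light: int
    n_dark: int
    ratio: float  # mean_light / mean_dark, rounded to 1 decimal
    p_value: float  # NaN when the test is degenerate

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.p_value)


def glucosamine_content(assay: GlucosamineAssay) -> float:
    """Glucosamine in mg per g dry weight from the standard-curve reading."""
    return (assay.C * assay.V_f * assay.V_e) / (assay.W_e * assay.V_a * 1000.0)


def biomass_estimate(inp: BiomassInput) -> float:
    """Fungal biomass in g per kg substrate from glucosamine content."""
    return inp.G * inp.W_f / inp.W_s


def compare_conditions(
    light_reps: Sequence[float],
    dark_reps: Sequence[float],
    equal_var: bool = True,
) -> ConditionComparison:
    """Two-sample t-test and ratio between light and dark replicates.

    Uses the equal-variance Student's form by default (``equal_var=False``
    switches to Welch).  The ratio mean_light/mean_dark is rounded to one
    decimal and requires mean_dark > 0.  When both samples are constant the
    p-value is undefined and reported as NaN.
    """
    light = np.asarray(light_reps, dtype=float)
    dark = np.asarray(dark_reps, dtype=float)
    if len(light) < 2 or len(dark) < 2:
        raise ValueError("need >= 2 replicates per condition")
    m_l, m_d = float(light.mean()), float(dark.mean())
    if m_d <= 0:
        raise ValueError("ratio undefined: dark mean must be positive")
    if light.std(ddof=1) == 0 and dark.std(ddof=1) == 0:
        p = float("nan")
    else:
        _, p = stats.ttest_ind(light, dark, equal_var=equal_var)
        p = float(p)
    return ConditionComparison(
        mean_light=m_l,
        mean_dark=m_d,
        sd_light=float(light.std(ddof=1)),
        sd_dark=float(dark.std(ddof=1)),
        n_light=len(light),
        n_dark=len(dark),
        ratio=round(m_l / m_d, 1),
        p_value=p,
    )


def summarize_assays(measurements: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Condition-comparison table from long-format replicate measurements.

    ``measurements`` has columns (condition, replicate, analyte, value)
    with conditions 'light' and 'dark'.  One row per analyte:
    mean +/- sd per condition, light/dark ratio, t-test p-value and a
    significance star at p <= alpha.
    """
    required = {"condition", "replicate", "analyte", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    rows = []
    for analyte, grp in measurements.groupby("analyte", sort=True):
        light = grp.loc[grp["condition"] == "light", "value"].to_numpy(dtype=float)
        dark = grp.loc[grp["condition"] == "dark", "value"].to_numpy(dtype=float)
        cmp = compare_conditions(light, dark)
        star = "*" if (not math.isnan(cmp.p_value) and cmp.p_value <= alpha) else ""
        rows.append(
            {
                "analyte": analyte,
                "light": f"{cmp.mean_light:.3f} ± {cmp.sd_light:.2f}",
                "dark": f"{cmp.mean_dark:.3f} ± {cmp.sd_dark:.2f}",
                "ratio": cmp.ratio,
                "p_value": cmp.p_value,
                "significant": star,
            }
        )
    return pd.DataFrame(rows)
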