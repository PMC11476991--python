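"""Published desk-scale reference measurements for *C. militaris* TBRC6039.

Small tables transcribed from the published light/dark cultivation study
this pipeline reanalyses: per-sample RNA-seq summary statistics and the
metabolite/biomass condition summaries.  These serve as inputs for the
summary-statistics and assay-comparison stages; genome-scale inputs (hit
tables, networks, counts) are generated synthetically instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "seq_run_summary",
    "metabolite_summary",
    "reconstruct_replicates",
]


def seq_run_summary() -> pd.DataFrame:
    """Per-sample sequencing and mapping statistics (two replicates each of
    dark D and light L).

    Columns: total clean reads (millions), %GC, uniquely mapped reads
    (millions) and the uniquely-mapped percentage.  The mapped percentage
    is taken from the per-sample mapped-read figures (95.71, 95.48, 95.84,
    95.99).
    """
    return pd.DataFrame(
        {
            "clean_reads_M": [24.88, 19.96, 22.25, 24.48],
            "gc_percent": [56.00, 56.00, 56.00, 57.00],
            "unique_mapped_M": [23.81, 19.05, 21.32, 23.50],
            "unique_mapped_percent": [95.71, 95.48, 95.84, 95.99],
        },
        index=["D-1", "D-2", "L-1", "L-2"],
    )


def metabolite_summary() -> pd.DataFrame:
    """Biomass and metabolite content by condition, as mean and sd (n = 3).

    Units: biomass g/kg; cordycepin and carotenoid mg per g cell mass.
    """
    return pd.DataFrame(
        {
            "analyte": ["biomass", "biomass", "cordycepin", "cordycepin", "carotenoid", "carotenoid"],
            "condition": ["dark", "light"] * 3,
            "mean": [57.857, 74.376, 13.014, 23.294, 0.092, 1.916],
            "sd": [4.67, 3.35, 0.04, 0.80, 0.05, 0.09],
            "n": [3] * 6,
        }
    )


def reconstruct_replicates(mean: float, sd: float, n: int = 3) -> list[float]:
    """Replicate values that exactly reproduce a reported mean and sample sd.

    The study reports only summary statistics; for t-tests on those
    summaries, a symmetric triple (mean - d, mean, mean + d) with
    d = sd * sqrt((n - 1) / 2) has precisely the stated mean and ddof-1 sd
    for n = 3.  Only defined for n = 3.
    """
    if n != 3:
        raise ValueError("replicate reconstruction is defined for n = 3")
    d = sd * np.sqrt((n - 1) / 2.0)
    return [mean - d, mean, mean + d]
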