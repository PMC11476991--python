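#!/usr/bin/env python
"""Desk-scale reproductions: sequencing-run summary and metabolite assays.

Recomputes the per-condition sequencing summary means from the published
per-sample values, the light/dark metabolite comparisons (cordycepin,
carotenoid, biomass) with Student's t-tests, and worked examples of the
glucosamine and biomass formulas.  Writes results/assays/.
"""

from pathlib import Path

import pandas as pd

from cmlight.assays import (
    BiomassInput,
    GlucosamineAssay,
    biomass_estimate,
    glucosamine_content,
    summarize_assays,
)
from cmlight.datasets import metabolite_summary, reconstruct_replicates, seq_run_summary
from cmlight.expression import replicate_summary

OUT = Path(__file__).resolve().parent.parent / "results" / "assays"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    runs = seq_run_summary()
    summary = replicate_summary(runs)
    print("sequencing-run summary (mean over the four samples):")
    print(summary.to_string())
    summary.to_csv(OUT / "seq_run_summary.tsv", sep="\t")

    rows = []
    for _, r in metabolite_summary().iterrows():
        for i, v in enumerate(reconstruct_replicates(r["mean"], r["sd"])):
            rows.append({"condition": r["condition"], "replicate": i + 1,
                         "analyte": r["analyte"], "value": v})
    table = summarize_assays(pd.DataFrame(rows))
    print("\nlight vs dark comparisons (mean ± sd, ratio, t-test):")
    print(table.to_string(index=False))
    table.to_csv(OUT / "condition_comparisons.tsv", sep="\t", index=False)

    # worked formula examples
    g = glucosamine_content(GlucosamineAssay(C=850.0, V_f=10.0, V_e=5.0, V_a=1.0, W_e=0.5))
    b = biomass_estimate(BiomassInput(G=g, W_f=8.7, W_s=10.0))
    print(f"\nglucosamine example: C=850 ug/mL, V_f=10, V_e=5, V_a=1 mL, "
          f"W_e=0.5 g -> {g:.1f} mg/gDW")
    print(f"biomass example: G={g:.1f} mg/gDW, W_f=8.7 g, W_s=10 g -> {b:.1f} g/kg")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
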