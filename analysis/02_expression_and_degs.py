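#!/usr/bin/env python
"""Expression processing: counts -> FPKM -> expressed genes -> DEG calls.

Simulates negative-binomial counts with planted two-fold-squared (log2FC 2)
light/dark effects, computes FPKM, summarises replicates by geometric
means, bins genes into the four expression categories, calls expressed
genes (mean FPKM >= 1) and their light/dark Venn partition, then applies
the DEG gate |log2FC| >= 1 and FDR < 0.001 to moderated t statistics.
Writes tables under results/expression/.
"""

import json
from pathlib import Path

from cmlight import deg, expression, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "expression"
SEED = 20240802


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    counts, lengths, truth = synthetic.gen_expression(
        n_genes=2000, n_reps_per_condition=5,
        frac_deg=0.11, effect_log2fc=2.0, dispersion=0.05, seed=SEED,
    )
    sample_condition = synthetic.sample_conditions(counts)
    filtered, fstats = expression.count_filter(counts)
    print(f"count filter (>=5 reads in >=1 sample): kept {fstats['n_kept']}, "
          f"dropped {fstats['n_dropped']}")

    fpkm = expression.compute_fpkm(filtered, lengths)
    means = expression.condition_means(fpkm, sample_condition)
    summary = expression.classify_and_call(means, conditions=["dark", "light"])
    cat_counts = {
        c: summary.category[c].value_counts().to_dict() for c in means.columns
    }
    print(f"expression categories: {cat_counts}")
    print(f"expressed-gene Venn (dark-only, light-only, both): {summary.venn}; "
          f"total expressed {summary.n_expressed_total}")

    stats = deg.moderated_deg_stats(fpkm, sample_condition)
    calls, counts_deg = deg.call_degs(stats)
    planted = truth.true_deg_up | truth.true_deg_down
    up = set(calls.loc[calls["call"] == "up", "gene"])
    down = set(calls.loc[calls["call"] == "down", "gene"])
    hits = (up & truth.true_deg_up) | (down & truth.true_deg_down)
    print(f"DEGs at |log2FC|>=1, FDR<0.001: {counts_deg} "
          f"(planted {len(planted)}, recovered {len(hits)})")

    # term enrichment on the upregulated set against a synthetic annotation
    import numpy as np

    rng = np.random.default_rng(SEED)
    universe = set(calls["gene"])
    terms = {}
    for t in range(12):
        terms[f"TERM{t:02d}"] = {
            str(g) for g in rng.choice(sorted(universe), size=120, replace=False)
        }
    terms["TERM_UP"] = set(rng.choice(sorted(truth.true_deg_up), size=60, replace=False)) | {
        str(g) for g in rng.choice(sorted(universe), size=40, replace=False)
    }
    enr = deg.hypergeometric_enrichment(up, terms, universe)
    n_sig = int(enr["significant"].sum())
    print(f"enrichment: {n_sig} terms at raw p < 0.05; top term "
          f"{enr['term'].iloc[0]} (p={enr['pvalue'].iloc[0]:.3g})")

    fpkm.round(4).to_csv(OUT / "fpkm.tsv", sep="\t")
    means.round(4).to_csv(OUT / "condition_means.tsv", sep="\t")
    calls.to_csv(OUT / "deg_calls.tsv", sep="\t", index=False)
    enr.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    (OUT / "venn.json").write_text(json.dumps(summary.venn, indent=2, sort_keys=True) + "\n")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
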