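#!/usr/bin/env python
"""Reconstruct an expanded regulatory network from synthetic sources.

Generates two template PPI networks with a known ortholog mapping to the
target gene set, recovers the orthologs by bidirectional best hits
(identity >= 25 %, E-value <= 1e-10), transfers the template interactions,
filters them to TF-TF edges, and merges them with the prior directed
network and a ChIP-derived regulator edge set.  Writes the eGRN and its
summary under results/egrn/.
"""

import json
from pathlib import Path

from cmlight import grn, orthology, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "egrn"
SEED = 20240801


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    gs_edges, truth = synthetic.gen_grn(
        n_tfs=40, n_targets=400, hub_count=5,
        hub_out_degree=60, background_out_degree=2, seed=SEED,
    )
    tf_set = {e[0] for e in gs_edges}
    target_ids = sorted({n for e in gs_edges for n in e})
    print(f"prior network: {len(gs_edges)} directed edges, {len(tf_set)} TFs")

    interolog_edges = []
    for k, name in enumerate(["templateA", "templateB"]):
        t_edges, t_ids = synthetic.gen_template_ppi(150, 400, seed=SEED + k + 1, prefix=f"{name}_")
        fwd, rev, orth_truth = synthetic.gen_ortholog_hits(
            t_ids, target_ids, frac_orthologous=0.6, noise=0.2, seed=SEED + 10 * (k + 1)
        )
        pairs = orthology.bidirectional_best_hits(
            orthology.best_hits(fwd), orthology.best_hits(rev)
        )
        found = {(p.template_id, p.target_id) for p in pairs}
        print(
            f"{name}: {len(t_edges)} template edges, BBH found {len(found)} "
            f"ortholog pairs (planted {len(orth_truth.ortholog_pairs)}, "
            f"exact match: {found == orth_truth.ortholog_pairs})"
        )
        orthology.write_ortholog_pairs(pairs, OUT / f"orthologs_{name}.tsv")
        interolog_edges.extend(grn.transfer_interactions(t_edges, pairs, name))

    tf_tf, stats = grn.filter_tf_tf(interolog_edges, tf_set, reference_nodes=set(target_ids))
    print(f"interolog TF-TF network: {stats['n_edges']} edges, {stats['n_nodes']} nodes, "
          f"{stats['n_new_nodes']} new nodes")

    chip_tf = sorted(truth.hub_tfs)[0]
    chip_edges = [(chip_tf, g) for g in sorted({t for _, t in gs_edges})[:25]]
    egrn = grn.assemble_egrn(gs_edges, tf_tf, chip_edges, tf_set)
    print(f"eGRN: {egrn.summary()}")

    grn.write_edges_tsv(egrn.edges, OUT / "egrn_edges.tsv")
    grn.write_graphml(egrn, OUT / "egrn.graphml")
    grn.write_sif(egrn.edges, OUT / "egrn.sif")
    (OUT / "summary.json").write_text(json.dumps(egrn.summary(), indent=2, sort_keys=True) + "\n")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
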