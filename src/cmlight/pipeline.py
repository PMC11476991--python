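"""End-to-end synthetic run of the eGRN / light-response pipeline.

Wires every stage together on generated inputs with known ground truth:

1. two template PPI networks and alignment hit tables against the target
   proteome -> BBH orthologs -> interolog transfer -> TF-TF filter,
2. eGRN assembly from a prior directed network, the interolog TF-TF edges
   and a ChIP-derived regulator edge set,
3. NB counts -> FPKM -> condition means / expressed-gene calls -> stand-in
   DEG statistics -> significance calls,
4. DEG overlay -> light-responsive subnetwork -> betweenness -> potential
   TF ranking -> regulated fraction,

and writes all tables deterministically, so two runs with the same seed
produce byte-identical outputs.  Planted hub TFs are assigned to planted
upregulated slots when expression ids are mapped onto network nodes —
light-responsive regulators are themselves differentially expressed — so
the planted regulatory signal is recoverable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deg, expression, grn, orthology, subnetwork, synthetic

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Problem sizes and study conditions for a synthetic run."""

    n_template_proteins: int = 150
    n_template_edges: int = 400
    frac_orthologous: float = 0.6
    noise: float = 0.2
    n_tfs: int = 40
    n_targets: int = 400
    hub_count: int = 5
    hub_out_degree: int = 60
    background_out_degree: int = 2
    n_chip_targets: int = 25
    n_reps_per_condition: int = 5
    frac_deg: float = 0.11
    effect_log2fc: float = 2.0
    dispersion: float = 0.05


@dataclass
class PipelineResult:
    summary: dict = field(default_factory=dict)
    egrn: grn.GRN | None = None
    sub: subnetwork.Subnetwork | None = None
    ranked_tfs: pd.DataFrame | None = None
    truth: synthetic.SyntheticTruth | None = None


def _map_genes_to_nodes(
    counts: pd.DataFrame,
    truth: synthetic.SyntheticTruth,
    node_ids: list[str],
    hub_tfs: set[str],
    seed: int,
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Rename synthetic expression genes onto network node ids.

    Hub TFs are placed on planted upregulated slots; everything else is
    shuffled deterministically.
    """
    rng = np.random.default_rng(seed)
    genes = list(counts.index)
    up = sorted(truth.true_deg_up)
    down = sorted(truth.true_deg_down)
    hubs = sorted(hub_tfs)
    if len(up) < len(hubs):
        raise ValueError("not enough planted upregulated genes to host the hub TFs")

    mapping: dict[str, str] = {}
    for g, tf in zip(up[: len(hubs)], hubs):
        mapping[g] = tf
    remaining_nodes = [n for n in node_ids if n not in hubs]
    rng.shuffle(remaining_nodes)
    remaining_genes = [g for g in genes if g not in mapping]
    for g, n in zip(remaining_genes, remaining_nodes):
        mapping[g] = n

    renamed = counts.rename(index=mapping)
    up_nodes = {mapping[g] for g in up if g in mapping}
    down_nodes = {mapping[g] for g in down if g in mapping}
    return renamed, up_nodes, down_nodes


def run_pipeline(
    seed: int, outdir: str | Path | None = None, config: PipelineConfig | None = None
) -> PipelineResult:
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed}

    # --- prior regulatory network with planted hubs -----------------------
    gs_edges, grn_truth = synthetic.gen_grn(
        cfg.n_tfs,
        cfg.n_targets,
        cfg.hub_count,
        cfg.hub_out_degree,
        cfg.background_out_degree,
        seed=seed,
    )
    tf_set = {e[0] for e in gs_edges} | grn_truth.hub_tfs
    node_ids = sorted({n for e in gs_edges for n in e})

    # --- orthology and interolog transfer from two templates --------------
    interolog_edges: list[grn.Edge] = []
    bbh_prec_rec: dict[str, float] = {}
    for k, name in enumerate(["templateA", "templateB"]):
        t_edges, t_ids = synthetic.gen_template_ppi(
            cfg.n_template_proteins, cfg.n_template_edges, seed=seed + 11 * (k + 1), prefix=f"{name}_"
        )
        fwd, rev, orth_truth = synthetic.gen_ortholog_hits(
            t_ids,
            node_ids,
            frac_orthologous=cfg.frac_orthologous,
            noise=cfg.noise,
            seed=seed + 17 * (k + 1),
        )
        pairs = orthology.bidirectional_best_hits(
            orthology.best_hits(fwd), orthology.best_hits(rev)
        )
        found = {(p.template_id, p.target_id) for p in pairs}
        planted = orth_truth.ortholog_pairs
        bbh_prec_rec[f"bbh_precision_{name}"] = (
            len(found & planted) / len(found) if found else 1.0
        )
        bbh_prec_rec[f"bbh_recall_{name}"] = (
            len(found & planted) / len(planted) if planted else 1.0
        )
        interolog_edges.extend(grn.transfer_interactions(t_edges, pairs, name))
        if out is not None:
            orthology.write_hits(fwd, out / f"hits_fwd_{name}.tsv")
            orthology.write_hits(rev, out / f"hits_rev_{name}.tsv")
            orthology.write_ortholog_pairs(pairs, out / f"ortholog_pairs_{name}.tsv")
    summary.update(bbh_prec_rec)

    tf_tf_edges, tf_tf_stats = grn.filter_tf_tf(
        interolog_edges, tf_set, reference_nodes=set(node_ids)
    )
    summary["interolog_tf_tf"] = tf_tf_stats

    # --- ChIP-derived regulator edges (photoreceptor analogue) ------------
    rng = np.random.default_rng(seed + 23)
    chip_tf = sorted(grn_truth.hub_tfs)[0] if grn_truth.hub_tfs else sorted(tf_set)[0]
    gene_pool = sorted({t for _, t in gs_edges})
    chip_targets = [str(g) for g in rng.choice(gene_pool, size=min(cfg.n_chip_targets, len(gene_pool)), replace=False)]
    chip_edges = [(chip_tf, g) for g in chip_targets]

    egrn = grn.assemble_egrn(gs_edges, tf_tf_edges, chip_edges, tf_set)
    summary["egrn"] = egrn.summary()
    if out is not None:
        grn.write_edges_tsv(egrn.edges, out / "egrn_edges.tsv")
        grn.write_graphml(egrn, out / "egrn.graphml")
        grn.write_sif(egrn.edges, out / "egrn.sif")

    # --- expression, FPKM, DEG calls --------------------------------------
    all_nodes = sorted(egrn.nodes)
    counts, lengths, expr_truth = synthetic.gen_expression(
        n_genes=len(all_nodes),
        n_reps_per_condition=cfg.n_reps_per_condition,
        frac_deg=cfg.frac_deg,
        effect_log2fc=cfg.effect_log2fc,
        dispersion=cfg.dispersion,
        seed=seed + 31,
    )
    lengths.index = counts.index
    counts, up_nodes, down_nodes = _map_genes_to_nodes(
        counts, expr_truth, all_nodes, grn_truth.hub_tfs, seed=seed + 37
    )
    lengths = lengths.rename(index=dict(zip(lengths.index, counts.index)))
    sample_condition = synthetic.sample_conditions(counts)

    filtered, filter_stats = expression.count_filter(counts)
    fpkm = expression.compute_fpkm(filtered, lengths)
    means = expression.condition_means(fpkm, sample_condition)
    cond_summary = expression.classify_and_call(means, conditions=["dark", "light"])
    summary["count_filter"] = filter_stats
    summary["venn_expressed"] = cond_summary.venn
    summary["n_expressed_total"] = cond_summary.n_expressed_total

    stats = deg.moderated_deg_stats(fpkm, sample_condition, condition_pair=("light", "dark"))
    calls, deg_counts = deg.call_degs(stats)
    summary["deg_counts"] = deg_counts
    called_up = set(calls.loc[calls["call"] == "up", "gene"])
    called_down = set(calls.loc[calls["call"] == "down", "gene"])
    planted = up_nodes | down_nodes
    recovered = (called_up & up_nodes) | (called_down & down_nodes)
    summary["deg_recall"] = len(recovered) / len(planted) if planted else 1.0

    if out is not None:
        counts.to_csv(out / "counts.tsv", sep="\t")
        fpkm.round(4).to_csv(out / "fpkm.tsv", sep="\t")
        means.round(4).to_csv(out / "condition_means.tsv", sep="\t")
        calls.to_csv(out / "deg_calls.tsv", sep="\t", index=False)
        (out / "venn.json").write_text(
            json.dumps(cond_summary.venn, indent=2, sort_keys=True) + "\n"
        )

    # --- light-responsive subnetwork and TF ranking ------------------------
    sub = subnetwork.extract_subnetwork(egrn, calls, mode="both_endpoints")
    summary["subnetwork"] = {"n_nodes": sub.n_nodes, "n_edges": sub.n_edges}
    if sub.n_nodes:
        b_raw = subnetwork.betweenness(sub)
        b_norm = subnetwork.normalize_betweenness(b_raw)
        ranked = subnetwork.rank_potential_tfs(sub, b_norm)
        top = list(ranked["tf"].head(cfg.hub_count))
        n_union, pct = subnetwork.regulated_fraction(top, sub)
        summary["potential_tfs"] = top
        summary["regulated_union"] = n_union
        summary["regulated_percent"] = pct
        hubs_found = [t for t in ranked["tf"] if t in grn_truth.hub_tfs]
        summary["hubs_in_ranking"] = len(hubs_found)
        if out is not None:
            ranked.round({"b_norm": 4}).to_csv(out / "potential_tfs.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "node": sorted(b_raw),
                    "b_raw": [round(b_raw[n], 6) for n in sorted(b_raw)],
                    "b_norm": [round(b_norm[n], 6) for n in sorted(b_raw)],
                }
            ).to_csv(out / "centrality.tsv", sep="\t", index=False)
            subnetwork.write_subnetwork_graphml(sub, b_norm, out / "subnetwork.graphml")
            subnetwork.write_subnetwork_sif(sub, out / "subnetwork.sif")
    else:
        ranked = pd.DataFrame(columns=["tf", "deg_call", "n_regulated", "b_norm"])

    truth = synthetic.SyntheticTruth(
        hub_tfs=grn_truth.hub_tfs,
        true_deg_up=up_nodes,
        true_deg_down=down_nodes,
        seed=seed,
    )
    if out is not None:
        synthetic.write_truth_json(truth, out / "truth.json")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
        )
    return PipelineResult(summary=summary, egrn=egrn, sub=sub, ranked_tfs=ranked, truth=truth)
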