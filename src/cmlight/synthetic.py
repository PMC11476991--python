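"""Synthetic input generators with recorded ground truth.

Every pipeline input — template PPI networks, alignment hit tables,
RNA-seq count matrices, and regulatory networks with planted hub TFs — can
be generated here with a known truth object, so each downstream stage is
testable without external databases or sequencing archives.

What the generators emulate (and what they do not): template PPI edge
lists stand in for curated fungal interactomes; hit tables emulate BLASTp
tabular output with reciprocal planted orthologs and two flavours of decoy
(threshold-failing and passing-but-non-reciprocal); counts follow a
negative-binomial model (variance mu + phi * mu^2), the standard RNA-seq
count model, with planted fold changes between dark and light conditions.
Reads, alignment, ChIP peaks and circadian time courses are not simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .orthology import HitRecord

__all__ = [
    "SyntheticTruth",
    "gen_template_ppi",
    "gen_ortholog_hits",
    "gen_expression",
    "gen_grn",
    "write_truth_json",
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators.

    ``ortholog_pairs`` is injective in both directions; the planted DEG
    sets are disjoint; ``hub_tfs`` is a subset of the generated TF list.
    """

    ortholog_pairs: set = field(default_factory=set)
    hub_tfs: set = field(default_factory=set)
    true_deg_up: set = field(default_factory=set)
    true_deg_down: set = field(default_factory=set)
    seed: int = 0

    def __post_init__(self) -> None:
        templates = [t for t, _ in self.ortholog_pairs]
        targets = [c for _, c in self.ortholog_pairs]
        if len(set(templates)) != len(templates) or len(set(targets)) != len(targets):
            raise ValueError("ortholog_pairs must be injective in both directions")
        if self.true_deg_up & self.true_deg_down:
            raise ValueError("planted up/down DEG sets must be disjoint")


def gen_template_ppi(
    n_proteins: int,
    n_edges: int,
    seed: int,
    prefix: str = "P",
) -> tuple[list[tuple[str, str]], list[str]]:
    """Random simple undirected PPI edge list on ``n_proteins`` nodes.

    No self-loops, no duplicate edges; deterministic for a fixed seed.
    """
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} exceeds the {max_edges} possible simple edges "
            f"on {n_proteins} proteins"
        )
    ids = [f"{prefix}{i:05d}" for i in range(n_proteins)]
    rng = np.random.default_rng(seed)
    # sample unordered index pairs without replacement via flat pair indexing
    chosen = rng.choice(max_edges, size=n_edges, replace=False) if n_edges else []
    edges = []
    for flat in sorted(int(c) for c in chosen):
        # invert the triangular index: flat -> (i, j), i < j
        i = int((1 + math.isqrt(1 + 8 * flat)) // 2)
        j = flat - i * (i - 1) // 2
        edges.append((ids[j], ids[i]))
    return edges, ids


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def gen_ortholog_hits(
    template_ids: Sequence[str],
    target_ids: Sequence[str],
    frac_orthologous: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[HitRecord], list[HitRecord], SyntheticTruth]:
    """Forward/reverse hit tables with planted reciprocal orthologs.

    A fraction ``frac_orthologous`` of the smaller proteome is paired; each
    planted pair appears as the reciprocal best hit with identity >= 40 %
    and E-value log-uniform in [1e-180, 1e-11].  Decoy hits (rate ``noise``
    per query) come in two flavours: threshold-failing (identity < 25 % or
    E-value in [1e-9, 1]) and passing-but-non-reciprocal, which either sit
    behind the planted best hit of a paired query or point an unpaired
    query at an already-paired subject.  By construction the downstream BBH
    stage recovers exactly the planted pairs.
    """
    if not template_ids or not target_ids:
        raise ValueError("template_ids and target_ids must be non-empty")
    if not 0.0 <= frac_orthologous <= 1.0:
        raise ValueError("frac_orthologous must lie in [0, 1]")
    if noise < 0:
        raise ValueError("noise must be non-negative")

    rng = np.random.default_rng(seed)
    n_pairs = round(frac_orthologous * min(len(template_ids), len(target_ids)))
    paired_templates = [str(x) for x in rng.choice(template_ids, size=n_pairs, replace=False)]
    paired_targets = [str(x) for x in rng.choice(target_ids, size=n_pairs, replace=False)]
    pairs = list(zip(paired_templates, paired_targets))
    t2c = dict(pairs)
    c2t = {c: t for t, c in pairs}

    fwd: list[HitRecord] = []
    rev: list[HitRecord] = []
    planted_ev: dict[str, float] = {}
    for t, c in pairs:
        ev_f = _log_uniform(rng, 1e-180, 1e-11)
        ev_r = _log_uniform(rng, 1e-180, 1e-11)
        planted_ev[t] = ev_f
        planted_ev[c] = ev_r
        fwd.append(HitRecord(t, c, float(rng.uniform(40, 95)), ev_f, float(rng.uniform(200, 1000))))
        rev.append(HitRecord(c, t, float(rng.uniform(40, 95)), ev_r, float(rng.uniform(200, 1000))))

    def add_decoys(queries, subjects, paired_subjects, subject_partner, out):
        for q in queries:
            if rng.uniform() >= noise:
                continue
            passing = bool(rng.uniform() < 0.5)
            if passing and q in planted_ev:
                # worse than the planted best hit but still under the cutoff
                lo = math.log10(planted_ev[q]) + 0.5
                ev = float(10 ** rng.uniform(lo, -10.2))
                others = [s for s in subjects if s != (t2c.get(q) or c2t.get(q))]
                if not others:
                    continue
                s = str(rng.choice(others))
                out.append(HitRecord(q, s, float(rng.uniform(30, 90)), ev, float(rng.uniform(50, 400))))
            elif passing and paired_subjects:
                # unpaired query hitting a subject whose reciprocal best is elsewhere
                s = str(rng.choice(paired_subjects))
                ev = _log_uniform(rng, 1e-60, 1e-11)
                out.append(HitRecord(q, s, float(rng.uniform(30, 90)), ev, float(rng.uniform(50, 400))))
            else:
                # threshold-failing decoy
                s = str(rng.choice(subjects))
                if rng.uniform() < 0.5:
                    out.append(HitRecord(q, s, float(rng.uniform(5, 24.9)), _log_uniform(rng, 1e-60, 1e-11), 60.0))
                else:
                    out.append(HitRecord(q, s, float(rng.uniform(30, 90)), _log_uniform(rng, 1e-9, 1.0), 40.0))

    add_decoys(list(template_ids), list(target_ids), paired_targets, t2c, fwd)
    add_decoys(list(target_ids), list(template_ids), paired_templates, c2t, rev)

    truth = SyntheticTruth(ortholog_pairs=set(pairs), seed=seed)
    return fwd, rev, truth


def gen_expression(
    n_genes: int,
    n_reps_per_condition: int,
    frac_deg: float = 0.1,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
    base_mean_log: float = math.log(500.0),
    base_mean_sigma: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Negative-binomial count matrix with planted light/dark fold changes.

    Baseline per-gene means are log-normal; a fraction ``frac_deg`` of
    genes (half up, half down) has its light-condition mean multiplied or
    divided by ``2 ** effect_log2fc``.  Counts are NB with variance
    mu + dispersion * mu^2 (Poisson when dispersion = 0).  Gene lengths
    are uniform in [300, 10000] bp.  Samples are named D_i / L_i.
    """
    if n_reps_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    if not 0.0 <= frac_deg <= 1.0:
        raise ValueError("frac_deg must lie in [0, 1]")
    if frac_deg > 0 and effect_log2fc < 1.0:
        raise ValueError("effect_log2fc must be >= 1 so planted DEGs are callable")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=base_mean_log, sigma=base_mean_sigma, size=n_genes)

    n_deg = round(frac_deg * n_genes)
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    up_idx = deg_idx[: n_deg // 2 + n_deg % 2]
    down_idx = deg_idx[n_deg // 2 + n_deg % 2 :]

    mu_dark = base.copy()
    mu_light = base.copy()
    mu_light[up_idx] *= 2.0 ** effect_log2fc
    mu_light[down_idx] /= 2.0 ** effect_log2fc

    def draw(mu: np.ndarray, n_reps: int) -> np.ndarray:
        mu_mat = np.tile(mu[:, None], (1, n_reps))
        if dispersion <= 0:
            return rng.poisson(mu_mat)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu_mat))

    dark = draw(mu_dark, n_reps_per_condition)
    light = draw(mu_light, n_reps_per_condition)
    samples = [f"D_{i + 1}" for i in range(n_reps_per_condition)] + [
        f"L_{i + 1}" for i in range(n_reps_per_condition)
    ]
    counts = pd.DataFrame(np.hstack([dark, light]), index=genes, columns=samples)
    lengths = pd.Series(rng.integers(300, 10001, size=n_genes), index=genes, name="length_bp")
    truth = SyntheticTruth(
        true_deg_up={genes[i] for i in up_idx},
        true_deg_down={genes[i] for i in down_idx},
        seed=seed,
    )
    return counts, lengths, truth


def sample_conditions(counts: pd.DataFrame) -> dict[str, str]:
    """Condition labels for the D_i / L_i sample naming convention."""
    return {s: ("dark" if s.startswith("D_") else "light") for s in counts.columns}


def gen_grn(
    n_tfs: int,
    n_targets: int,
    hub_count: int,
    hub_out_degree: int,
    background_out_degree: int,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Directed TF->gene network with planted high-out-degree hub TFs.

    ``hub_count`` TFs regulate ``hub_out_degree`` distinct targets each;
    the remaining TFs regulate ``background_out_degree`` targets.
    Deterministic per seed.
    """
    if hub_count > n_tfs:
        raise ValueError("hub_count cannot exceed n_tfs")
    if hub_count > 0:
        if hub_out_degree <= background_out_degree:
            raise ValueError("hub_out_degree must exceed background_out_degree")
        if hub_out_degree > n_targets:
            raise ValueError("hub_out_degree cannot exceed n_targets")
    if background_out_degree > n_targets:
        raise ValueError("background_out_degree cannot exceed n_targets")

    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:04d}" for i in range(n_tfs)]
    genes = [f"G{i:05d}" for i in range(n_targets)]
    hubs = {str(t) for t in rng.choice(tfs, size=hub_count, replace=False)} if hub_count else set()

    edges: list[tuple[str, str]] = []
    for tf in tfs:
        k = hub_out_degree if tf in hubs else background_out_degree
        if k == 0 or not genes:
            continue
        targets = rng.choice(genes, size=k, replace=False)
        edges.extend((tf, str(g)) for g in targets)
    truth = SyntheticTruth(hub_tfs=hubs, seed=seed)
    return edges, truth


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "ortholog_pairs": sorted(list(p) for p in truth.ortholog_pairs),
        "hub_tfs": sorted(truth.hub_tfs),
        "true_deg_up": sorted(truth.true_deg_up),
        "true_deg_down": sorted(truth.true_deg_down),
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
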