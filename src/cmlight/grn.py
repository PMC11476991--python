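"""Interolog transfer and expanded gene regulatory network (eGRN) assembly.

Template protein-protein interactions are transferred to the target species
through BBH ortholog pairs (the interolog assumption: orthologs of
interacting proteins interact), filtered to TF-TF edges, and merged with a
prior genome-scale GRN and a ChIP-derived regulator->target edge set into a
single expanded network.

Interolog edges are undirected (physical-interaction semantics); prior-GRN
and ChIP edges are directed (regulation semantics).  Both are stored
losslessly with a per-edge ``directed`` flag, and the interaction total
counts each unordered node pair once.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .orthology import OrthologPair

__all__ = [
    "Edge",
    "GRN",
    "transfer_interactions",
    "filter_tf_tf",
    "assemble_egrn",
    "tf_family_summary",
    "write_edges_tsv",
    "write_sif",
    "write_graphml",
]


@dataclass(frozen=True)
class Edge:
    """A network edge with direction flag and provenance tags.

    ``provenance`` is a sorted tuple of tags such as ``gsGRN``,
    ``interolog:<template>`` or ``chip``; an edge supported by several
    sources carries all their tags.
    """

    source: str
    target: str
    directed: bool
    provenance: tuple[str, ...]

    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair, used for interaction-level deduplication."""
        return (self.source, self.target) if self.directed else tuple(sorted((self.source, self.target)))


@dataclass
class GRN:
    """Directed/mixed regulatory network with node roles.

    ``nodes`` maps node id -> {"is_tf": bool, "is_regulated": bool}.
    """

    nodes: dict[str, dict[str, bool]] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    tf_families: dict[str, str] = field(default_factory=dict)

    @property
    def tf_set(self) -> set[str]:
        return {n for n, a in self.nodes.items() if a["is_tf"]}

    @property
    def n_tfs(self) -> int:
        return len(self.tf_set)

    @property
    def n_regulated(self) -> int:
        return sum(1 for a in self.nodes.values() if a["is_regulated"])

    @property
    def n_interactions(self) -> int:
        """Number of distinct unordered node pairs connected by any edge."""
        return len({tuple(sorted((e.source, e.target))) for e in self.edges})

    def summary(self) -> dict[str, int]:
        return {
            "n_nodes": len(self.nodes),
            "n_edges": len(self.edges),
            "n_interactions": self.n_interactions,
            "n_tfs": self.n_tfs,
            "n_regulated": self.n_regulated,
        }


def _as_mapping(ortholog_pairs) -> dict[str, str]:
    if isinstance(ortholog_pairs, Mapping):
        mapping = dict(ortholog_pairs)
    else:
        mapping = {}
        for p in ortholog_pairs:
            if isinstance(p, OrthologPair):
                mapping[p.template_id] = p.target_id
            else:
                t, c = p[0], p[1]
                mapping[t] = c
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("ortholog mapping is not injective (duplicate targets)")
    return mapping


def transfer_interactions(
    template_edges: Iterable[tuple[str, str]],
    ortholog_pairs,
    template_name: str,
) -> list[Edge]:
    """Transfer template PPI edges through an ortholog mapping.

    For each template edge (P, Q) with ortholog targets p, q (both mapped,
    p != q) an undirected edge (p, q) tagged ``interolog:<template_name>``
    is emitted.  Self-loops (p == q) are dropped and duplicates collapsed.
    Output size is therefore <= the template edge count.
    """
    mapping = _as_mapping(ortholog_pairs)
    tag = f"interolog:{template_name}"
    seen: set[tuple[str, str]] = set()
    out: list[Edge] = []
    for p_t, q_t in template_edges:
        p, q = mapping.get(p_t), mapping.get(q_t)
        if p is None or q is None or p == q:
            continue
        key = tuple(sorted((p, q)))
        if key in seen:
            continue
        seen.add(key)
        out.append(Edge(source=key[0], target=key[1], directed=False, provenance=(tag,)))
    return out


def filter_tf_tf(
    edges: Iterable[Edge],
    tf_set: set[str],
    reference_nodes: set[str] | None = None,
) -> tuple[list[Edge], dict[str, int]]:
    """Retain edges whose two endpoints are both TFs.

    Returns the filtered edge list plus a stats dict with the node count
    and, when ``reference_nodes`` is given, the count of nodes absent from
    that reference set ("new nodes", e.g. TFs not present in the prior GRN).
    """
    if not tf_set:
        raise ValueError("tf_set must be non-empty")
    kept = [e for e in edges if e.source in tf_set and e.target in tf_set]
    nodes = {e.source for e in kept} | {e.target for e in kept}
    stats = {"n_edges": len(kept), "n_nodes": len(nodes)}
    if reference_nodes is not None:
        stats["n_new_nodes"] = len(nodes - reference_nodes)
    return kept, stats


def _merge_provenance(edges: Iterable[Edge]) -> list[Edge]:
    """Collapse identical (source, target, directed) records, merging tags."""
    merged: dict[tuple[str, str, bool], set[str]] = {}
    for e in edges:
        s, t = (e.source, e.target) if e.directed else tuple(sorted((e.source, e.target)))
        merged.setdefault((s, t, e.directed), set()).update(e.provenance)
    return [
        Edge(source=s, target=t, directed=d, provenance=tuple(sorted(tags)))
        for (s, t, d), tags in sorted(merged.items())
    ]


def assemble_egrn(
    gsgrn_edges: Iterable[tuple[str, str]],
    interolog_tf_edges: Iterable[Edge],
    chip_edges: Iterable[tuple[str, str]],
    tf_set: set[str],
    tf_families: Mapping[str, str] | None = None,
) -> GRN:
    """Merge the three edge sources into one expanded GRN.

    Prior-network (``gsgrn_edges``) and ChIP (``chip_edges``) records are
    directed regulator->target pairs; interolog edges are undirected
    :class:`Edge` records.  Identical records from different sources are
    collapsed with merged provenance; a directed and an undirected record
    between the same pair stay distinct but count once in the interaction
    total.  A ChIP regulator missing from the TF list is kept with a
    warning and promoted to TF.

    Node roles: ``is_tf`` iff in the (possibly extended) TF set;
    ``is_regulated`` iff the node has an incoming directed edge or is the
    non-TF endpoint of an undirected edge whose other endpoint is a TF.
    """
    tf_set = set(tf_set)
    records: list[Edge] = []
    for s, t in gsgrn_edges:
        records.append(Edge(source=s, target=t, directed=True, provenance=("gsGRN",)))
    records.extend(interolog_tf_edges)
    for s, t in chip_edges:
        if s not in tf_set:
            warnings.warn(
                f"ChIP regulator {s!r} is not in the TF list; adding it",
                stacklevel=2,
            )
            tf_set.add(s)
        records.append(Edge(source=s, target=t, directed=True, provenance=("chip",)))

    edges = _merge_provenance(records)
    node_ids = sorted({e.source for e in edges} | {e.target for e in edges})

    regulated: set[str] = set()
    for e in edges:
        if e.directed:
            regulated.add(e.target)
        else:
            if e.source in tf_set and e.target not in tf_set:
                regulated.add(e.target)
            if e.target in tf_set and e.source not in tf_set:
                regulated.add(e.source)

    nodes = {
        n: {"is_tf": n in tf_set, "is_regulated": n in regulated} for n in node_ids
    }
    families = {n: f for n, f in (tf_families or {}).items() if n in tf_set}
    return GRN(nodes=nodes, edges=edges, tf_families=families)


def tf_family_summary(
    tf_families: Mapping[str, str],
    tf_set: set[str],
    top_k: int = 5,
) -> tuple[dict[str, int], list[tuple[str, int]]]:
    """Tally TF family sizes over a TF set; unmapped TFs count as "unclassified".

    Returns the full family -> count table (counts sum to ``|tf_set|``) and
    the top-k families by count, ties broken lexicographically.
    """
    counts: dict[str, int] = {}
    for tf in tf_set:
        fam = tf_families.get(tf, "unclassified")
        counts[fam] = counts.get(fam, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return counts, ranked[:top_k]


# ---------------------------------------------------------------------------
# export


def write_edges_tsv(edges: Iterable[Edge], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tdirected\tprovenance\n")
        for e in edges:
            fh.write(f"{e.source}\t{e.target}\t{int(e.directed)}\t{';'.join(e.provenance)}\n")


def write_sif(edges: Iterable[Edge], path: str | Path) -> None:
    """Simple interaction format for Cytoscape; relation is pp/reg."""
    with Path(path).open("w") as fh:
        for e in edges:
            rel = "reg" if e.directed else "pp"
            fh.write(f"{e.source}\t{rel}\t{e.target}\n")


def write_graphml(grn: GRN, path: str | Path) -> None:
    """GraphML export with node roles and edge provenance as attributes."""
    g = nx.DiGraph()
    for n in sorted(grn.nodes):
        a = grn.nodes[n]
        g.add_node(n, is_tf=a["is_tf"], is_regulated=a["is_regulated"])
    for e in grn.edges:
        g.add_edge(
            e.source,
            e.target,
            directed=e.directed,
            provenance=";".join(e.provenance),
        )
    nx.write_graphml(g, str(path))


def write_summary_json(grn: GRN, path: str | Path) -> None:
    Path(path).write_text(json.dumps(grn.summary(), indent=2, sort_keys=True) + "\n")
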