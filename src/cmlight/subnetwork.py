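"""Light-responsive subnetwork extraction and betweenness-based TF ranking.

DEG calls are overlaid on the expanded GRN; the condition-specific
subnetwork keeps (by default) only edges whose two endpoints are both
significant DEGs.  Node importance is the betweenness centrality

    B(n) = sum over unordered pairs i != j != n of sigma_ij(n) / sigma_ij

computed on the undirected, unweighted view of the subnetwork (pairs in
different components contribute 0), min-max normalised to [0, 1]:

    b_norm(n) = (B(n) - min B) / (max B - min B).

TFs with b_norm strictly above 0.1 are flagged as potential regulators and
ranked by their number of distinct regulated targets in the subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .expression import round_half_up
from .grn import GRN, Edge

__all__ = [
    "Subnetwork",
    "extract_subnetwork",
    "betweenness",
    "normalize_betweenness",
    "rank_potential_tfs",
    "regulated_fraction",
    "write_subnetwork_graphml",
    "write_subnetwork_sif",
]


@dataclass
class Subnetwork:
    """A DEG-induced slice of the GRN; every node sits on >= 1 retained edge."""

    nodes: dict[str, dict[str, object]] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def tf_set(self) -> set[str]:
        return {n for n, a in self.nodes.items() if a["is_tf"]}


def extract_subnetwork(
    grn: GRN,
    deg_table: pd.DataFrame,
    mode: str = "both_endpoints",
) -> Subnetwork:
    """Extract the condition-specific subnetwork from DEG calls.

    ``both_endpoints`` keeps edges whose two endpoints are both significant
    DEGs (call up or down); ``target_only`` keeps directed edges whose
    target is a DEG regardless of the regulator (undirected edges then need
    either endpoint significant).  Isolated nodes are dropped.
    """
    if mode not in ("both_endpoints", "target_only"):
        raise ValueError(f"unknown mode {mode!r}")
    calls = dict(zip(deg_table["gene"], deg_table["call"]))

    def is_deg(n: str) -> bool:
        return calls.get(n, "ns") in ("up", "down")

    kept: list[Edge] = []
    for e in grn.edges:
        if mode == "both_endpoints":
            keep = is_deg(e.source) and is_deg(e.target)
        else:
            keep = is_deg(e.target) if e.directed else (is_deg(e.source) or is_deg(e.target))
        if keep:
            kept.append(e)

    node_ids = sorted({e.source for e in kept} | {e.target for e in kept})
    nodes = {
        n: {
            "is_tf": grn.nodes.get(n, {"is_tf": False})["is_tf"],
            "deg_call": calls.get(n, "ns"),
        }
        for n in node_ids
    }
    return Subnetwork(nodes=nodes, edges=kept)


def _undirected_view(edges: Iterable[Edge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_node(e.source)
        g.add_node(e.target)
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    return g


def betweenness(
    network: Subnetwork | nx.Graph | Iterable[Edge],
    directed: bool = False,
) -> dict[str, float]:
    """Raw betweenness B(n) over unordered node pairs, unweighted.

    The default (and the convention used throughout) views all edges as
    undirected; ``directed=True`` uses the directed edges as given.
    Disconnected pairs contribute 0.
    """
    if isinstance(network, Subnetwork):
        edges: Iterable[Edge] = network.edges
    elif isinstance(network, (nx.Graph, nx.DiGraph)):
        g = network
        return {n: float(b) for n, b in nx.betweenness_centrality(g, normalized=False).items()}
    else:
        edges = list(network)
    if directed:
        g = nx.DiGraph()
        for e in edges:
            g.add_node(e.source)
            g.add_node(e.target)
            if e.source != e.target:
                g.add_edge(e.source, e.target)
                if not e.directed:
                    g.add_edge(e.target, e.source)
    else:
        g = _undirected_view(edges)
    return {n: float(b) for n, b in nx.betweenness_centrality(g, normalized=False).items()}


def normalize_betweenness(b_raw: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalise raw betweenness to [0, 1].

    The node with maximal B scores exactly 1 and the minimal node 0.  In
    the degenerate case where all scores are equal, every node scores 0
    and a warning is issued.
    """
    if not b_raw:
        raise ValueError("empty betweenness table")
    lo, hi = min(b_raw.values()), max(b_raw.values())
    if hi == lo:
        warnings.warn("all betweenness scores equal; normalised scores set to 0", stacklevel=2)
        return {n: 0.0 for n in b_raw}
    return {n: (b - lo) / (hi - lo) for n, b in b_raw.items()}


def rank_potential_tfs(
    subnetwork: Subnetwork,
    b_norm: Mapping[str, float],
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Rank potential TFs: b_norm strictly above the threshold.

    Columns: tf, deg_call, n_regulated (distinct targets of the TF's
    retained directed edges), b_norm.  Sorted by n_regulated descending,
    ties by b_norm descending, then id.
    """
    targets: dict[str, set[str]] = {}
    for e in subnetwork.edges:
        if e.directed and e.source in subnetwork.tf_set:
            targets.setdefault(e.source, set()).add(e.target)
    rows = []
    for tf in sorted(subnetwork.tf_set):
        score = b_norm.get(tf, 0.0)
        if score > threshold:
            rows.append(
                {
                    "tf": tf,
                    "deg_call": subnetwork.nodes[tf]["deg_call"],
                    "n_regulated": len(targets.get(tf, set())),
                    "b_norm": score,
                }
            )
    df = pd.DataFrame(rows, columns=["tf", "deg_call", "n_regulated", "b_norm"])
    if len(df):
        df = df.sort_values(
            ["n_regulated", "b_norm", "tf"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def regulated_fraction(
    top_tfs: Sequence[str],
    subnetwork: Subnetwork,
) -> tuple[int, int]:
    """Union of the top TFs' distinct targets and its share of subnetwork nodes.

    Returns (union size, percentage of subnetwork nodes, rounded half-up to
    an integer).  An empty TF list yields (0, 0).
    """
    missing = [t for t in top_tfs if t not in subnetwork.tf_set]
    if missing:
        raise ValueError(f"not TFs of the subnetwork: {missing}")
    union: set[str] = set()
    for e in subnetwork.edges:
        if e.directed and e.source in set(top_tfs):
            union.add(e.target)
    if not top_tfs or subnetwork.n_nodes == 0:
        return len(union), 0
    pct = int(round_half_up(100.0 * len(union) / subnetwork.n_nodes, 0))
    return len(union), pct


def write_subnetwork_graphml(
    subnetwork: Subnetwork, b_norm: Mapping[str, float], path: str | Path
) -> None:
    g = nx.DiGraph()
    for n in sorted(subnetwork.nodes):
        a = subnetwork.nodes[n]
        g.add_node(
            n,
            role="TF" if a["is_tf"] else "gene",
            deg_call=str(a["deg_call"]),
            b_norm=float(b_norm.get(n, 0.0)),
        )
    for e in subnetwork.edges:
        g.add_edge(e.source, e.target, directed=e.directed, provenance=";".join(e.provenance))
    nx.write_graphml(g, str(path))


def write_subnetwork_sif(subnetwork: Subnetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for e in subnetwork.edges:
            rel = "reg" if e.directed else "pp"
            fh.write(f"{e.source}\t{rel}\t{e.target}\n")
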