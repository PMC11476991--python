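"""Subnetwork extraction, betweenness centrality and potential-TF ranking."""

import warnings

import networkx as nx
import pandas as pd
import pytest

from cmlight import synthetic
from cmlight.grn import Edge, assemble_egrn
from cmlight.subnetwork import (
    Subnetwork,
    betweenness,
    extract_subnetwork,
    normalize_betweenness,
    rank_potential_tfs,
    regulated_fraction,
)
from conftest import bruteforce_betweenness


def directed(s, t):
    return Edge(source=s, target=t, directed=True, provenance=("gsGRN",))


def calls_frame(genes, call="up"):
    return pd.DataFrame({"gene": list(genes), "call": [call] * len(genes)})


def toy_grn(edges, tf_set):
    return assemble_egrn([(e.source, e.target) for e in edges], [], [], tf_set)


class TestExtract:
    def test_both_endpoints_rule(self):
        grn = toy_grn([directed("t1", "g1"), directed("t1", "g2")], {"t1"})
        sub = extract_subnetwork(grn, calls_frame(["t1", "g1"]))
        assert sub.n_edges == 1 and sub.n_nodes == 2
        assert set(sub.nodes) == {"t1", "g1"}

    def test_no_degs_gives_empty_subnetwork(self):
        grn = toy_grn([directed("t1", "g1")], {"t1"})
        sub = extract_subnetwork(grn, calls_frame([], "up"))
        assert sub.n_nodes == 0 and sub.n_edges == 0

    def test_target_only_ignores_regulator_state(self):
        grn = toy_grn([directed("t1", "g1")], {"t1"})
        sub = extract_subnetwork(grn, calls_frame(["g1"]), mode="target_only")
        assert sub.n_edges == 1

    def test_unknown_mode_rejected(self):
        grn = toy_grn([directed("t1", "g1")], {"t1"})
        with pytest.raises(ValueError):
            extract_subnetwork(grn, calls_frame(["g1"]), mode="nope")

    def test_matches_bruteforce_under_both_modes(self, rng_factory):
        rng = rng_factory(0)
        edges = [directed(f"t{rng.integers(6)}", f"g{rng.integers(40)}") for _ in range(150)]
        grn = toy_grn(edges, {f"t{i}" for i in range(6)})
        degs = {f"g{i}" for i in rng.choice(40, 15, replace=False)} | {"t0", "t3"}
        table = calls_frame(sorted(degs))
        for mode in ("both_endpoints", "target_only"):
            sub = extract_subnetwork(grn, table, mode=mode)
            if mode == "both_endpoints":
                expected = [e for e in grn.edges if e.source in degs and e.target in degs]
            else:
                expected = [e for e in grn.edges if e.target in degs]
            assert sorted((e.source, e.target) for e in sub.edges) == sorted(
                (e.source, e.target) for e in expected
            )

    def test_both_endpoints_subset_of_target_only_when_tfs_all_deg(self, rng_factory):
        rng = rng_factory(1)
        edges = [directed(f"t{rng.integers(5)}", f"g{rng.integers(30)}") for _ in range(80)]
        grn = toy_grn(edges, {f"t{i}" for i in range(5)})
        degs = {f"t{i}" for i in range(5)} | {f"g{i}" for i in rng.choice(30, 10, replace=False)}
        table = calls_frame(sorted(degs))
        both = extract_subnetwork(grn, table, mode="both_endpoints")
        tgt = extract_subnetwork(grn, table, mode="target_only")
        assert {(e.source, e.target) for e in both.edges} <= {
            (e.source, e.target) for e in tgt.edges
        }


class TestBetweenness:
    def test_path_graph(self):
        edges = [directed("A", "B"), directed("B", "C")]
        b = betweenness(edges)
        assert b == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_graph(self):
        edges = [directed("c", f"l{i}") for i in range(4)]
        b = betweenness(edges)
        assert b["c"] == 6.0  # C(4,2) leaf pairs, all through the center
        assert all(b[f"l{i}"] == 0.0 for i in range(4))

    def test_tree_equals_pair_count_through_node(self):
        # balanced binary tree: B(root) counts pairs split across subtrees
        g = nx.balanced_tree(2, 3)
        edges = [directed(str(u), str(v)) for u, v in g.edges]
        b = betweenness(edges)
        adj = {str(n): {str(m) for m in g.neighbors(n)} for n in g.nodes}
        ref = bruteforce_betweenness(adj)
        for n in b:
            assert b[n] == pytest.approx(ref[n], abs=1e-9)

    def test_extra_leaf_edge_lowers_center_score(self):
        star = [directed("c", f"l{i}") for i in range(4)]
        with_chord = star + [directed("l0", "l1")]
        assert betweenness(with_chord)["c"] < betweenness(star)["c"]

    def test_matches_enumeration_on_random_graphs(self, rng_factory):
        rng = rng_factory(2)
        for _ in range(10):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            edges = [directed(str(u), str(v)) for u, v in g.edges]
            if not edges:
                continue
            b = betweenness(edges)
            adj = {
                str(u): {str(v) for v in g.neighbors(u)}
                for u in g.nodes
                if g.degree[u] > 0
            }
            ref = bruteforce_betweenness(adj)
            for node in ref:
                assert b[node] == pytest.approx(ref[node], abs=1e-9)


class TestNormalize:
    def test_unique_max_scores_one(self):
        b = normalize_betweenness({"a": 0.0, "b": 7.3, "c": 2.0})
        assert b["b"] == 1.0 and b["a"] == 0.0

    def test_linear_map(self):
        assert normalize_betweenness({"a": 0, "b": 5, "c": 10}) == {
            "a": 0.0,
            "b": 0.5,
            "c": 1.0,
        }

    def test_constant_scores_degenerate_to_zero_with_warning(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = normalize_betweenness({"a": 3.0, "b": 3.0})
        assert out == {"a": 0.0, "b": 0.0}
        assert len(w) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_betweenness({})

    def test_invariant_to_affine_rescaling(self, rng_factory):
        rng = rng_factory(3)
        raw = {f"n{i}": float(rng.uniform(0, 50)) for i in range(20)}
        scaled = {k: 3.7 * v + 11.0 for k, v in raw.items()}
        a = normalize_betweenness(raw)
        b = normalize_betweenness(scaled)
        for k in raw:
            assert a[k] == pytest.approx(b[k], abs=1e-12)


class TestRanking:
    def make_subnetwork(self, edges, tf_set, call="up"):
        nodes = {}
        for e in edges:
            for n in (e.source, e.target):
                nodes[n] = {"is_tf": n in tf_set, "deg_call": call}
        return Subnetwork(nodes=nodes, edges=edges)

    def test_threshold_is_strict(self):
        edges = [directed("t1", "g1")]
        sub = self.make_subnetwork(edges, {"t1"})
        ranked = rank_potential_tfs(sub, {"t1": 0.1}, threshold=0.1)
        assert len(ranked) == 0
        ranked = rank_potential_tfs(sub, {"t1": 0.100001}, threshold=0.1)
        assert list(ranked["tf"]) == ["t1"]

    def test_empty_subnetwork(self):
        ranked = rank_potential_tfs(Subnetwork(), {})
        assert len(ranked) == 0

    def test_sorted_by_targets_then_score(self):
        edges = [directed("tA", f"g{i}") for i in range(3)] + [
            directed("tB", f"g{i}") for i in range(5)
        ]
        sub = self.make_subnetwork(edges, {"tA", "tB"})
        ranked = rank_potential_tfs(sub, {"tA": 0.9, "tB": 0.5})
        assert list(ranked["tf"]) == ["tB", "tA"]
        assert list(ranked["n_regulated"]) == [5, 3]

    def test_planted_hubs_outrank_background(self):
        for seed in range(3):
            gs_edges, truth = synthetic.gen_grn(12, 150, 3, 40, 2, seed=seed)
            grn = assemble_egrn(gs_edges, [], [], {e[0] for e in gs_edges})
            table = calls_frame(sorted(grn.nodes))
            sub = extract_subnetwork(grn, table)
            b_norm = normalize_betweenness(betweenness(sub))
            ranked = rank_potential_tfs(sub, b_norm)
            pos = {tf: i for i, tf in enumerate(ranked["tf"])}
            assert truth.hub_tfs <= set(pos)
            background = set(pos) - truth.hub_tfs
            for hub in truth.hub_tfs:
                assert all(pos[hub] < pos[b] for b in background)


class TestRegulatedFraction:
    def test_union_and_percent(self):
        edges = [directed("t1", "g1"), directed("t1", "g2"), directed("t2", "g2")]
        sub = TestRanking().make_subnetwork(edges, {"t1", "t2"})
        n, pct = regulated_fraction(["t1"], sub)
        assert n == 2 and pct == 50  # 2 of 4 nodes

    def test_no_top_tfs(self):
        edges = [directed("t1", "g1")]
        sub = TestRanking().make_subnetwork(edges, {"t1"})
        assert regulated_fraction([], sub) == (0, 0)

    def test_matches_bruteforce_union(self, rng_factory):
        rng = rng_factory(4)
        edges = [directed(f"t{rng.integers(4)}", f"g{rng.integers(25)}") for _ in range(60)]
        sub = TestRanking().make_subnetwork(edges, {f"t{i}" for i in range(4)})
        tops = ["t0", "t2"]
        n, pct = regulated_fraction(tops, sub)
        expected = {e.target for e in edges if e.source in tops}
        assert n == len(expected)
        import math

        assert pct == math.floor(100 * len(expected) / sub.n_nodes + 0.5)
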