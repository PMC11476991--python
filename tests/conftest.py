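"""Shared oracles for the test suite: independent brute-force references."""

from __future__ import annotations

from collections import defaultdict, deque
from itertools import combinations

import pytest


def bruteforce_best_hits(hits, min_identity=25.0, max_evalue=1e-10):
    """Reference best-hit scan: filter, then sort survivors per query."""
    per_query = defaultdict(list)
    for h in hits:
        if h.identity >= min_identity and h.evalue <= max_evalue:
            per_query[h.query_id].append(h)
    out = {}
    for q, rows in per_query.items():
        rows.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        out[q] = rows[0]
    return out


def bruteforce_bbh(fwd_hits, rev_hits, **kw):
    fwd = bruteforce_best_hits(fwd_hits, **kw)
    rev = bruteforce_best_hits(rev_hits, **kw)
    pairs = set()
    for t, h in fwd.items():
        r = rev.get(h.subject_id)
        if r is not None and r.subject_id == t:
            pairs.add((t, h.subject_id))
    return pairs


def bruteforce_betweenness(adjacency):
    """Naive betweenness by shortest-path counting from both endpoints.

    ``adjacency`` maps node -> set of neighbours (undirected).  For each
    unordered pair (i, j), sigma_ij(n) = sigma_in * sigma_nj when n lies on
    a shortest path; disconnected pairs contribute nothing.
    """

    def bfs_counts(src):
        dist = {src: 0}
        sigma = {src: 1}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        return dist, sigma

    nodes = sorted(adjacency)
    b = {n: 0.0 for n in nodes}
    info = {n: bfs_counts(n) for n in nodes}
    for i, j in combinations(nodes, 2):
        dist_i, sig_i = info[i]
        if j not in dist_i:
            continue
        d_ij = dist_i[j]
        total = sig_i[j]
        dist_j, sig_j = info[j]
        for n in nodes:
            if n in (i, j) or n not in dist_i or n not in dist_j:
                continue
            if dist_i[n] + dist_j[n] == d_ij:
                b[n] += sig_i[n] * sig_j[n] / total
    return b


def enumerate_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    annotated = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


@pytest.fixture
def rng_factory():
    import numpy as np

    return lambda seed: np.random.default_rng(seed)
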