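"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration, independently of
the package's implementation path, so tests compare two routes.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def brute_force_scores(records, regions, min_coverage=1):
    """Per-(gene, kind, context) weighted level by a per-record double loop."""
    num: dict = {}
    den: dict = {}
    for rec in records:
        if rec.meth + rec.unmeth < min_coverage or rec.meth + rec.unmeth == 0:
            continue
        for reg in regions:
            if reg.chrom == rec.chrom and reg.start <= rec.pos < reg.end:
                key = (reg.gene_id, reg.kind, rec.context)
                num[key] = num.get(key, 0) + rec.meth
                den[key] = den.get(key, 0) + rec.meth + rec.unmeth
    return {key: num[key] / den[key] for key in den if den[key] > 0}


def hypergeom_upper_tail_enumeration(k, N, K, n):
    """P[overlap >= k] by enumerating all C(N, n) draws from N labeled genes."""
    if k <= 0:
        return 1.0
    term = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_stepup(p_values):
    """Benjamini-Hochberg by the literal sorted step-up definition."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [None] * m
    running_min = math.inf
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def _all_shortest_paths(adjacency, source):
    """BFS distances and all shortest paths from one node."""
    dist = {source: 0}
    paths = {source: [[source]]}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                paths[v] = [p + [v] for p in paths[u]]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                paths[v].extend(p + [v] for p in paths[u])
    return dist, paths


def brute_force_centralities(nodes, edges):
    """All five centralities by explicit shortest-path enumeration."""
    nodes = list(nodes)
    n = len(nodes)
    adjacency = {v: set() for v in nodes}
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)

    out = {}
    all_dist = {}
    all_paths = {}
    for v in nodes:
        all_dist[v], all_paths[v] = _all_shortest_paths(adjacency, v)

    for v in nodes:
        degree = len(adjacency[v])
        reachable = all_dist[v]
        r = len(reachable)  # includes v itself
        total_dist = sum(reachable.values())
        closeness = (r - 1) / total_dist if total_dist > 0 else 0.0
        closeness_norm = (
            closeness * (r - 1) / (n - 1) if n > 1 else 0.0
        )
        betweenness = 0.0
        for s, t in itertools.combinations(nodes, 2):
            if s == v or t == v or t not in all_dist[s]:
                continue
            sigma = len(all_paths[s][t])
            sigma_v = sum(1 for p in all_paths[s][t] if v in p[1:-1])
            betweenness += sigma_v / sigma
        scale = (n - 1) * (n - 2) / 2
        out[v] = {
            "degree": float(degree),
            "degree_norm": degree / (n - 1) if n > 1 else 0.0,
            "closeness": closeness,
            "closeness_norm": closeness_norm,
            "betweenness": betweenness / scale if scale > 0 else 0.0,
        }
    return out


def venn_bitmask(named_sets):
    """Exclusive Venn regions by per-gene membership bitmasks."""
    names = [name for name, _ in named_sets]
    union = set().union(*(s for _, s in named_sets))
    regions: dict = {}
    for gene in union:
        mask = tuple(name for name, s in named_sets if gene in s)
        regions.setdefault(mask, set()).add(gene)
    return {mask: sorted(genes) for mask, genes in regions.items()}
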