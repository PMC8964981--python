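"""Independent brute-force oracles used to cross-check graph metrics and the
rank-sum test. Deliberately naive: BFS by hand, exhaustive enumeration of
triples, shortest paths and rank assignments. Kept free of any imports from
the package under test."""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


def bfs_distances(nodes, edges, source):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def shortest_path_counts(nodes, edges, source):
    """(distance, number of shortest paths) from source to every reachable node."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    order = []
    while queue:
        u = queue.popleft()
        order.append(u)
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def betweenness_oracle(nodes, edges):
    """Vertex betweenness (endpoints excluded, each unordered pair once) by
    explicit enumeration of all shortest paths through each vertex."""
    nodes = list(nodes)
    b = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sig_s = shortest_path_counts(nodes, edges, s)
        if t not in dist_s:
            continue
        dist_t, sig_t = shortest_path_counts(nodes, edges, t)
        d = dist_s[t]
        total = sig_s[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d:
                b[v] += sig_s[v] * sig_t[v] / total
    return b


def betweenness_centralization_oracle(nodes, edges):
    n = len(nodes)
    b = betweenness_oracle(nodes, edges)
    bmax = max(b.values())
    return sum(bmax - bi for bi in b.values()) / ((n - 1) ** 2 * (n - 2) / 2)


def transitivity_oracle(nodes, edges):
    eset = {frozenset(e) for e in edges}
    triangles = 0
    open_triples = 0
    for a, b_, c in itertools.combinations(list(nodes), 3):
        links = sum(
            1 for pair in ((a, b_), (a, c), (b_, c)) if frozenset(pair) in eset
        )
        if links == 3:
            triangles += 1  # contributes 3 connected triples
        elif links == 2:
            open_triples += 1
    total_triples = open_triples + 3 * triangles
    if total_triples == 0:
        return None
    return 3 * triangles / total_triples


def average_path_length_oracle(nodes, edges):
    total = 0
    pairs = 0
    for s, t in itertools.combinations(list(nodes), 2):
        dist = bfs_distances(nodes, edges, s)
        if t in dist:
            total += dist[t]
            pairs += 1
    if pairs == 0:
        raise ValueError("no reachable pairs")
    return total / pairs


def modularity_oracle(nodes, edges, partition):
    m = len(edges)
    communities = set(partition.values())
    degree = {v: 0 for v in nodes}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    q = 0.0
    for c in communities:
        members = {v for v in nodes if partition[v] == c}
        mc = sum(1 for u, v in edges if u in members and v in members)
        dc = sum(degree[v] for v in members)
        q += mc / m - (dc / (2 * m)) ** 2
    return q


def exact_ranksum_oracle(x, y):
    """Two-sided exact rank-sum p by itertools enumeration of all
    C(n+m, n) assignments of ranks to the first group."""
    n, m = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == n + m, "oracle requires no ties"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in x)
    sums = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
    total = comb(n + m, n)
    lower = sum(1 for s in sums if s <= w_obs) / total
    upper = sum(1 for s in sums if s >= w_obs) / total
    return min(1.0, 2 * min(lower, upper))
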