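"""Independent brute-force centrality implementations used as test oracles.

Deliberately naive: plain BFS, explicit shortest-path counting, dense power
iterations.  Nothing here calls networkx or the package under test.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_distances(adj: dict[int, set[int]], s: int) -> dict[int, int]:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def path_counts(adj: dict[int, set[int]], s: int) -> tuple[dict[int, int], dict[int, int]]:
    """(distances, number of shortest s→v paths) by BFS layer DP."""
    dist = bfs_distances(adj, s)
    sigma = {v: 0 for v in adj}
    sigma[s] = 1
    for v in sorted(dist, key=dist.get):
        if v == s:
            continue
        sigma[v] = sum(sigma[u] for u in adj[v] if u in dist and dist[u] == dist[v] - 1)
    return dist, sigma


def bf_degree(adj: dict[int, set[int]]) -> dict[int, float]:
    n = len(adj)
    return {v: (len(adj[v]) / (n - 1) if n > 1 else 0.0) for v in adj}


def bf_closeness(adj: dict[int, set[int]]) -> dict[int, float]:
    """Wasserman–Faust scaled closeness: ((k-1)/totsp)·((k-1)/(n-1))."""
    n = len(adj)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        k = len(dist)
        tot = sum(dist.values())
        out[v] = 0.0 if tot == 0 or n <= 1 else ((k - 1) / tot) * ((k - 1) / (n - 1))
    return out


def bf_betweenness(adj: dict[int, set[int]]) -> dict[int, float]:
    """Normalized betweenness via explicit σ_st(v) = σ_sv·σ_vt counting."""
    n = len(adj)
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    dists = {}
    sigmas = {}
    for s in nodes:
        dists[s], sigmas[s] = path_counts(adj, s)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dists[s] or sigmas[s][t] == 0:
                continue
            dst = dists[s][t]
            for v in nodes:
                if v in (s, t) or v not in dists[s] or v not in dists[t]:
                    continue
                if dists[s][v] + dists[t][v] == dst:
                    bc[v] += sigmas[s][v] * sigmas[t][v] / sigmas[s][t]
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: x * scale for v, x in bc.items()}
    return bc


def bf_eigenvector(adj: dict[int, set[int]], tol: float = 1e-15, max_iter: int = 500_000):
    """Perron vector of A by shifted power iteration on (A + I), unit 2-norm."""
    nodes = sorted(adj)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u in adj:
        for v in adj[u]:
            a[idx[u], idx[v]] = 1.0
    m = a + np.eye(n)
    x = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        nxt = m @ x
        nxt /= np.linalg.norm(nxt)
        if np.max(np.abs(nxt - x)) < tol:
            x = nxt
            break
        x = nxt
    x = np.abs(x)
    return dict(zip(nodes, (x / np.linalg.norm(x)).tolist()))


def bf_pagerank(adj: dict[int, set[int]], alpha: float = 0.85, tol: float = 1e-15):
    """Dense PageRank power iteration with uniform dangling redistribution."""
    nodes = sorted(adj)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    p = np.ones(n) / n
    out_deg = np.array([len(adj[v]) for v in nodes], dtype=float)
    for _ in range(100_000):
        nxt = np.zeros(n)
        dangling = 0.0
        for v in nodes:
            i = idx[v]
            if out_deg[i] == 0:
                dangling += p[i]
            else:
                share = p[i] / out_deg[i]
                for u in adj[v]:
                    nxt[idx[u]] += share
        nxt = alpha * (nxt + dangling / n) + (1 - alpha) / n
        if np.abs(nxt - p).sum() < tol:
            p = nxt
            break
        p = nxt
    return dict(zip(nodes, p.tolist()))


def graph_to_adj(g) -> dict[int, set[int]]:
    return {v: set(g.neighbors(v)) for v in g.nodes()}
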