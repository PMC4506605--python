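"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they validate: shortest
paths are counted by hand-rolled breadth-first search, and the log-log
regression is recomputed from closed-form least-squares sums.
"""

from __future__ import annotations

import math
from collections import deque


def bfs_counts(adj: dict, source):
    """Distances and shortest-path counts from *source* by plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                q.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def _adjacency(net) -> dict:
    adj = {n: set() for n in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def betweenness_oracle(net) -> dict:
    """Normalized betweenness by explicit pair-by-pair path counting."""
    adj = _adjacency(net)
    nodes = list(adj)
    n = len(nodes)
    info = {s: bfs_counts(adj, s) for s in nodes}
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    for i, s in enumerate(nodes):
        dist_s, sig_s = info[s]
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            d_st = dist_s[t]
            n_paths = sig_s[t]
            for v in nodes:
                if v is s or v is t:
                    continue
                dist_v, sig_v = info[v]
                if v in dist_s and t in dist_v and dist_s[v] + dist_v[t] == d_st:
                    bc[v] += sig_s[v] * sig_v[t] / n_paths
    scale = (n - 1) * (n - 2) / 2.0
    return {v: x / scale for v, x in bc.items()}


def closeness_oracle(net) -> dict:
    """Component-restricted closeness by BFS distance sums."""
    adj = _adjacency(net)
    out = {}
    for v in adj:
        dist, _ = bfs_counts(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def ols_loglog_oracle(ks, ps):
    """Closed-form OLS of log10(p) on log10(k): (slope, intercept, r_squared)."""
    xs = [math.log10(k) for k in ks]
    ys = [math.log10(p) for p in ps]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ss_res = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
    mean_y = sy / n
    ss_tot = sum((y - mean_y) ** 2 for y in ys)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2
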