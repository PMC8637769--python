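"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit BFS, recursive shortest-path
enumeration, triangle counting by set intersection, power iteration, and
exhaustive draw enumeration — so it shares no code path with the package.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: dict, s) -> dict:
    dist = {s: 0}
    q = deque([s])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def _all_shortest_paths(adj: dict, dist: dict, s, t) -> list[list]:
    """Every shortest s-t path, as node lists, by backwards recursion."""
    out: list[list] = []

    def back(u, acc):
        if u == s:
            out.append([s] + acc)
            return
        for w in adj[u]:
            if dist.get(w, -1) == dist[u] - 1:
                back(w, [u] + acc)

    back(t, [])
    return out


def betweenness_oracle(adj: dict) -> dict:
    """Unnormalized betweenness over unordered pairs via path enumeration."""
    nodes = list(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        if t not in dist:
            continue
        paths = _all_shortest_paths(adj, dist, s, t)
        sigma = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def closeness_oracle(adj: dict) -> dict:
    cc = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        cc[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return cc


def eigenvector_oracle(adj: dict, iters: int = 20000, tol: float = 1e-14) -> dict:
    nodes = list(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for v, nbrs in adj.items():
        for w in nbrs:
            a[idx[v], idx[w]] = 1.0
    # power-iterate on A + I: same eigenvectors, but the Perron value is
    # strictly dominant even on bipartite graphs (spectrum symmetric there)
    a = a + np.eye(len(nodes))
    x = np.ones(len(nodes))
    for _ in range(iters):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    if x.max() > 0:
        x = x / x.max()
    return {v: x[idx[v]] for v in nodes}


def lac_oracle(adj: dict) -> dict:
    out = {}
    for v, nbrs in adj.items():
        nbrs = set(nbrs)
        if not nbrs:
            out[v] = 0.0
            continue
        deg_within = sum(len(adj[w] & nbrs) for w in nbrs)
        out[v] = deg_within / len(nbrs)
    return out


def nc_oracle(adj: dict) -> dict:
    out = {}
    for v, nbrs in adj.items():
        total = 0.0
        for w in nbrs:
            denom = min(len(adj[v]) - 1, len(adj[w]) - 1)
            if denom <= 0:
                continue
            total += len(adj[v] & adj[w]) / denom
        out[v] = total
    return out


def graph_to_adj(g) -> dict:
    return {v: set(g.neighbors(v)) for v in g.nodes}


def hypergeom_tail_by_enumeration(N: int, K: int, n: int) -> dict[int, float]:
    """P(X >= k) for every k, by enumerating all C(N, n) draws."""
    marked = set(range(K))
    counts: dict[int, int] = {}
    total = 0
    for draw in combinations(range(N), n):
        k = len(marked.intersection(draw))
        counts[k] = counts.get(k, 0) + 1
        total += 1
    tails = {}
    for k in range(0, min(K, n) + 1):
        tails[k] = sum(c for kk, c in counts.items() if kk >= k) / total
    return tails


def expected_richness_by_enumeration(counts: list[int], n: int) -> float:
    """Mean #distinct taxa over all size-n subsamples of the reads."""
    reads = []
    for i, c in enumerate(counts):
        reads.extend([i] * c)
    vals = [len(set(sub)) for sub in combinations(range(len(reads)), n)
            for sub in [tuple(reads[j] for j in sub)]]
    return float(np.mean(vals))
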