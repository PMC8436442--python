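"""Independent exhaustive implementations of the graph measures.

Everything here is deliberately naive — triple/path enumeration and
Floyd-Warshall on dense matrices — so it can serve as an oracle for the
vectorized implementations on small graphs.  Nothing imports from
wmconnect's metric code.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_distances(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by Floyd-Warshall; lengths[i,j] = 0 means no edge."""
    n = lengths.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                d[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def edge_lengths(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    if not weighted:
        return (adjacency > 0).astype(float)
    with np.errstate(divide="ignore"):
        return np.where(adjacency > 0, 1.0 / adjacency, 0.0)


def brute_clustering(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    """Per-node clustering by enumerating all neighbor pairs."""
    a = (adjacency > 0).astype(int)
    n = a.shape[0]
    out = np.zeros(n)
    wmax = adjacency.max() if weighted else 1.0
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, l in itertools.combinations(nbrs, 2):
            if weighted:
                if a[j, l]:
                    total += (
                        (adjacency[i, j] / wmax)
                        * (adjacency[i, l] / wmax)
                        * (adjacency[j, l] / wmax)
                    ) ** (1.0 / 3.0)
            else:
                total += a[j, l]
        out[i] = 2.0 * total / (k * (k - 1))
    return out


def brute_path_metrics(adjacency: np.ndarray, weighted: bool):
    """(lp over finite ordered pairs, eglob, nodal efficiency)."""
    d = floyd_distances(edge_lengths(adjacency, weighted))
    n = d.shape[0]
    finite, inv = [], np.zeros_like(d)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                finite.append(d[i, j])
                inv[i, j] = 1.0 / d[i, j]
    lp = float(np.mean(finite)) if finite else np.inf
    eglob = inv[~np.eye(n, dtype=bool)].mean()
    nodal_eff = inv.sum(axis=1) / (n - 1)
    return lp, float(eglob), nodal_eff


def brute_betweenness(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    """Betweenness by enumerating every shortest path with DFS.

    Equal-length paths share credit equally; each unordered pair is counted
    once.
    """
    lengths = edge_lengths(adjacency, weighted)
    d = floyd_distances(lengths)
    n = adjacency.shape[0]
    out = np.zeros(n)

    def all_shortest_paths(s, t):
        paths = []

        def dfs(node, dist, path):
            if node == t:
                paths.append(list(path))
                return
            for nxt in range(n):
                if lengths[node, nxt] > 0 and nxt not in path:
                    nd = dist + lengths[node, nxt]
                    # prune: the path so far plus the remaining distance must
                    # equal the shortest s-t distance
                    if np.isfinite(d[nxt, t]) and abs(nd + d[nxt, t] - d[s, t]) < 1e-9:
                        path.append(nxt)
                        dfs(nxt, nd, path)
                        path.pop()

        dfs(s, 0.0, [s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]):
                continue
            paths = all_shortest_paths(s, t)
            for p in paths:
                for v in p[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def brute_local_efficiency(adjacency: np.ndarray, weighted: bool) -> np.ndarray:
    a = adjacency > 0
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if a[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adjacency[np.ix_(nbrs, nbrs)]
        _, eglob, _ = brute_path_metrics(sub, weighted)
        out[i] = eglob
    return out


def random_graph(rng: np.random.Generator, n: int, weighted: bool, p: float = 0.5):
    """A random symmetric adjacency with zero diagonal for oracle tests."""
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(len(iu)) < p
    w = rng.uniform(0.1, 1.0, size=len(iu)) if weighted else np.ones(len(iu))
    w = np.where(present, w, 0.0)
    adj = np.zeros((n, n))
    adj[iu, ju] = w
    adj[ju, iu] = w
    return adj
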