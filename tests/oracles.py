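"""Brute-force reference implementations used only to check the library.

Deliberately naive (triple loops, exhaustive enumeration) and independent
of the code paths they validate.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the classic O(N^3) relaxation."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_per_node(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering by exhaustive neighbor-pair enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        d = len(nbrs)
        if d < 2:
            continue
        links = sum(
            adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1:]
        )
        out[i] = links / (d * (d - 1) / 2)
    return out


def characteristic_path_length(adj: np.ndarray) -> tuple[float, int]:
    """Mean finite off-diagonal distance and the disconnected-pair count."""
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)), len(vals) - len(finite)


def global_efficiency(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])
        ) / (n - 1)
    return out


def local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def pearson_pairwise(x: np.ndarray) -> np.ndarray:
    """Correlation matrix from the textbook per-pair formula."""
    t, n = x.shape
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = x[:, i] - x[:, i].mean()
            b = x[:, j] - x[:, j].mean()
            r[i, j] = r[j, i] = (a @ b) / np.sqrt((a @ a) * (b @ b))
    return r


def ols_residuals_normal_equations(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals via the explicit normal equations."""
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return y - design @ beta


def trapezoid(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal rule written out knot by knot."""
    total = 0.0
    for k in range(len(grid) - 1):
        total += 0.5 * (values[k] + values[k + 1]) * (grid[k + 1] - grid[k])
    return total


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring of n nodes, each linked to its k nearest neighbors (k even)."""
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for step in range(1, k // 2 + 1):
            j = (i + step) % n
            adj[i, j] = adj[j, i] = 1
    return adj


def random_graph(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Erdos-Renyi adjacency matrix (symmetric, hollow)."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1).astype(np.uint8)
    return adj | adj.T
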