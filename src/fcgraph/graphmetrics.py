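"""Topological metrics on binary brain networks.

Implements the five measures used to characterize cost-thresholded
functional networks:

- Cp, the mean clustering coefficient (local segregation): per node,
  the fraction of neighbor pairs that are themselves connected,
  E_i / (D_i (D_i - 1) / 2), averaged over all N nodes (degree < 2
  contributes 0, keeping the 1/N prefactor exact).
- Lp, the characteristic path length (global integration): the mean
  shortest-path length over connected ordered node pairs; disconnected
  pairs are excluded and counted in a fragmentation report.
- Eglobal, global efficiency: the mean of 1/L_ij over ordered pairs with
  the 1/inf = 0 convention, so fragmentation is handled naturally.
- Elocal, local efficiency (fault tolerance): the mean over nodes of the
  global efficiency of each node's neighbor-induced subgraph.
- Enodal, nodal efficiency: per node, the mean inverse distance to every
  other node; its mean over nodes equals Eglobal identically.

Shortest paths are unweighted breadth-first distances via
``scipy.sparse.csgraph``; everything operates on validated undirected
simple graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from .netbuild import BinaryNetwork


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return BinaryNetwork(np.asarray(net), cost=0.5).adjacency  # validates


@dataclass
class GlobalMetrics:
    """Scalar network measures at one cost."""

    cost: float
    Cp: float
    Lp: float
    Eglobal: float
    Elocal: float
    n_disconnected_pairs: int = 0

    @property
    def fragmented(self) -> bool:
        return self.n_disconnected_pairs > 0


@dataclass
class NodalMetrics:
    """Per-node measures at one cost."""

    cost: float
    Enodal: np.ndarray
    degree: np.ndarray
    clustering: np.ndarray
    region_labels: list[str] = field(default_factory=list)


def shortest_paths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs unweighted distances (float matrix, inf for disconnected pairs)."""
    a = _adj(net)
    d = _sp_shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    return d


def clustering_coefficient(
    net: BinaryNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-node clustering values and their mean Cp.

    Node value = (triangles through the node) / (D_i (D_i - 1) / 2);
    nodes with degree < 2 contribute 0. Cp is the mean over all N nodes.
    """
    a = _adj(net).astype(float)
    deg = a.sum(axis=1)
    tri = ((a @ a) * a).sum(axis=1) / 2.0  # diag(A^3)/2, one matmul
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> tuple[float, int]:
    """Mean shortest-path length over connected ordered pairs.

    Returns (Lp, number of disconnected ordered pairs). For a connected
    graph this is exactly sum(L_ij) / (N (N-1)). Raises if no pair is
    connected (fully isolated graph).
    """
    d = shortest_paths(net) if distances is None else distances
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    n_inf = int((~finite).sum())
    if not finite.any():
        raise ValueError("no connected node pair: path length undefined")
    return float(vals[finite].mean()), n_inf


def global_efficiency(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> float:
    """Mean of 1/L_ij over ordered pairs (1/inf = 0)."""
    d = shortest_paths(net) if distances is None else distances
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    return float(np.where(np.isfinite(inv), inv, 0.0).sum() / (n * (n - 1)))


def nodal_efficiency(
    net: BinaryNetwork | np.ndarray, distances: np.ndarray | None = None
) -> np.ndarray:
    """Per-node mean inverse distance to all other nodes (1/inf = 0).

    The mean of this vector over nodes equals the global efficiency.
    """
    d = shortest_paths(net) if distances is None else distances
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


@njit(cache=True)
def _local_efficiency_kernel(adj):  # pragma: no cover - jit
    n = adj.shape[0]
    total = 0.0
    nbrs = np.empty(n, np.int64)
    for i in range(n):
        m = 0
        for j in range(n):
            if adj[i, j]:
                nbrs[m] = j
                m += 1
        if m < 2:
            continue
        sub = np.empty((m, m), np.uint8)
        for a in range(m):
            for b in range(m):
                sub[a, b] = adj[nbrs[a], nbrs[b]]
        # breadth-first all-pairs inverse-distance sum within the subgraph
        inv_sum = 0.0
        dist = np.empty(m, np.int64)
        queue = np.empty(m, np.int64)
        for s in range(m):
            for q in range(m):
                dist[q] = -1
            dist[s] = 0
            queue[0] = s
            head, tail = 0, 1
            while head < tail:
                u = queue[head]
                head += 1
                for v in range(m):
                    if sub[u, v] == 1 and dist[v] < 0:
                        dist[v] = dist[u] + 1
                        queue[tail] = v
                        tail += 1
            for q in range(m):
                if q != s and dist[q] > 0:
                    inv_sum += 1.0 / dist[q]
        total += inv_sum / (m * (m - 1))
    return total / n


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor-induced subgraph.

    Nodes with fewer than two neighbors contribute 0. The per-node
    breadth-first searches run in a compiled kernel; the brute-force
    subgraph construction in the test oracles checks it.
    """
    return float(_local_efficiency_kernel(_adj(net)))


def global_metrics(net: BinaryNetwork, cost: float | None = None) -> GlobalMetrics:
    """All scalar measures for one network, sharing one distance computation."""
    d = shortest_paths(net)
    _, cp = clustering_coefficient(net)
    lp, n_inf = characteristic_path_length(net, distances=d)
    return GlobalMetrics(
        cost=net.cost if cost is None else cost,
        Cp=cp,
        Lp=lp,
        Eglobal=global_efficiency(net, distances=d),
        Elocal=local_efficiency(net),
        n_disconnected_pairs=n_inf,
    )


def nodal_metrics(
    net: BinaryNetwork, region_labels: list[str] | None = None
) -> NodalMetrics:
    """Per-node degree, clustering, and nodal efficiency for one network."""
    d = shortest_paths(net)
    clust, _ = clustering_coefficient(net)
    return NodalMetrics(
        cost=net.cost,
        Enodal=nodal_efficiency(net, distances=d),
        degree=net.adjacency.sum(axis=1).astype(int),
        clustering=clust,
        region_labels=region_labels or [],
    )
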