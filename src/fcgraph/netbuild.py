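"""Functional-connectivity matrices and cost-thresholded binary networks.

Edges are defined from the Pearson correlation between region time series,
Fisher z-transformed; networks are binarized at fixed *cost* (edge density:
existing edges over the N(N-1)/2 possible), so every subject's graph has
the same number of edges at a given threshold and topology can be compared
without correlation-level confounds. The default sweep covers costs 0.10 to
0.40 in steps of 0.01 (31 thresholds, endpoints included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .signalprep import RoiTimeSeries

logger = logging.getLogger(__name__)

DEFAULT_COST_GRID = np.round(np.arange(0.10, 0.401, 0.01), 2)


@dataclass
class ConnectivityMatrix:
    """Per-subject N x N correlation (r) and Fisher-z (z) matrices.

    ``r`` is symmetric with unit diagonal; ``z = atanh(r)`` with |r| clamped
    to 1 - 1e-15 first so z stays finite off the diagonal.
    """

    subject_id: str
    r: np.ndarray
    z: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, m in (("r", self.r), ("z", self.z)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError(f"{name} is not symmetric within 1e-12")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| exceeds 1")
        off = ~np.eye(self.z.shape[0], dtype=bool)
        if not np.all(np.isfinite(self.z[off])):
            raise ValueError("non-finite off-diagonal z value")
        if not self.region_labels:
            self.region_labels = [f"ROI_{i + 1:03d}" for i in range(self.r.shape[0])]

    @property
    def n_rois(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected, unweighted graph at one cost: a hollow symmetric 0/1 matrix."""

    adjacency: np.ndarray
    cost: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if not np.all((a == 0) | (a == 1)):
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class BinaryNetworkSweep:
    """One subject's stack of binary networks over an increasing cost grid."""

    subject_id: str
    costs: np.ndarray
    networks: list[BinaryNetwork]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.costs) <= 0):
            raise ValueError("cost grid must be strictly increasing")
        if len(self.networks) != len(self.costs):
            raise ValueError("one network per cost required")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform atanh(r), with |r| clamped to 1 - 1e-15 (clamps logged)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("|r| exceeds 1")
    clamp = 1.0 - 1e-15
    n_clamped = int(np.sum(np.abs(r_arr) >= clamp))
    if n_clamped:
        logger.info("fisher_z: clamped %d value(s) with |r| ~ 1", n_clamped)
    z = np.arctanh(np.clip(r_arr, -clamp, clamp))
    return z if np.ndim(r) else float(z)


def pearson_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """All-pairs Pearson correlation of region signals, plus its Fisher-z map.

    Raises
    ------
    ValueError
        If any region's signal has zero variance (names the region).
    """
    sd = ts.values.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region signal(s): {bad}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = np.asarray(fisher_z(r))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(ts.subject_id, r, z, list(ts.region_labels))


def edge_count_for_cost(n_nodes: int, cost: float) -> int:
    """Edges at a given cost: round(cost * N(N-1)/2), rounding half up."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(cost * max_edges + 0.5))


def _ranked_pairs(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by decreasing |z|, ties by lexicographic (i, j)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    absz = np.abs(z[iu, ju])
    order = np.lexsort((ju, iu, -absz))
    return iu[order], ju[order], absz[order]


def threshold_at_cost(cm: ConnectivityMatrix, cost: float) -> BinaryNetwork:
    """Binarize at fixed cost: keep the E = round(cost * N(N-1)/2) largest-|z| edges.

    Rank thresholding (by edge count, not a fixed z cut) equates densities
    across subjects. Ties at the cut are broken by lexicographic (i, j)
    order and logged.
    """
    if not 0 < cost < 1:
        raise ValueError("cost must be in (0, 1)")
    n = cm.n_rois
    max_edges = n * (n - 1) // 2
    e = edge_count_for_cost(n, cost)
    if e == 0 or e == max_edges:
        raise ValueError(
            f"degenerate network at cost={cost}: {e} of {max_edges} edges"
        )
    ii, jj, absz = _ranked_pairs(cm.z)
    if e < absz.size and absz[e - 1] == absz[e]:
        logger.info(
            "threshold_at_cost: tie at the cut (|z|=%.6g), broken lexicographically",
            absz[e - 1],
        )
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:e], jj[:e]] = 1
    adj |= adj.T
    return BinaryNetwork(adj, float(cost), cm.subject_id)


def sweep(
    cm: ConnectivityMatrix, grid: np.ndarray | None = None
) -> BinaryNetworkSweep:
    """Threshold one connectivity matrix at every cost of the grid.

    The default grid is the 31 costs 0.10, 0.11, ..., 0.40. Because rank
    thresholding with a deterministic tie-break selects a prefix of one
    fixed edge ordering, the edge sets are nested across increasing costs.
    """
    grid = DEFAULT_COST_GRID if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("cost grid must lie in (0, 1)")
    nets = [threshold_at_cost(cm, c) for c in grid]
    return BinaryNetworkSweep(cm.subject_id, grid, nets)
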