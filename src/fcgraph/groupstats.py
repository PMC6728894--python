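"""Group-level statistics: AUC summaries, permutation tests, NBS, regressions.

Metric curves over the cost sweep are collapsed to one scalar per subject by
the trapezoidal area under the curve (AUC). Group differences are assessed
nonparametrically: the observed two-sample t statistic (pooled variance) is
referenced against an empirical null built by randomly reassigning subjects
to groups (group sizes preserved); the two-sided p-value uses the add-one
estimator p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), so it is never
exactly zero.

Edge-level inference operates on the pre-threshold Fisher-z values (t tests
on binarized edges would be ill-posed). Two family-wise corrections are
offered: Bonferroni on parametric edge p-values, and the network-based
statistic (NBS), which thresholds edges at a primary p, extracts connected
components, and calibrates the maximal component size by permutation.

Brain-behavior associations are partial correlations: metric and behavior
are both residualized on covariates (plus intercept), and the Pearson r of
the residuals is tested against a t distribution with n - K - 2 degrees of
freedom (K covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


@dataclass
class GroupResult:
    metric: str
    t_observed: float
    p_perm: float
    n_permutations: int
    significant: bool
    direction: str = ""  # "increased"/"decreased" in group B relative to A


@dataclass
class EdgeFinding:
    region_i: str
    region_j: str
    t: float
    p: float
    direction: str
    component_id: int | None = None


# ---------------------------------------------------------------- AUC


def metric_auc(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal area under a metric curve over the cost grid.

    Requires a finite value at every grid point (no silent interpolation).
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("one value per cost required")
    if not np.all(np.isfinite(values)):
        bad = grid[~np.isfinite(values)]
        raise ValueError(f"non-finite metric values at costs {bad.tolist()}")
    return float(np.trapezoid(values, grid))


# ------------------------------------------------- permutation machinery


def _pooled_t(sum_a, sumsq_a, n_a, sum_b, sumsq_b, n_b):
    """Two-sample pooled-variance t from group sums and sums of squares."""
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a**2
    ss_b = sumsq_b - n_b * mean_b**2
    sp2 = (ss_a + ss_b) / (n_a + n_b - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return (mean_a - mean_b) / denom


def _perm_indicator(n: int, n_a: int, n_perm: int, rng: np.random.Generator):
    """(n_perm, n) 0/1 matrix; each row marks a random size-n_a 'group A'."""
    base = np.tile(np.arange(n), (n_perm, 1))
    perm = rng.permuted(base, axis=1)
    ind = np.zeros((n_perm, n))
    np.put_along_axis(ind, perm[:, :n_a], 1.0, axis=1)
    return ind


def permutation_t_matrix(
    data: np.ndarray,
    n_a: int,
    n_perm: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted pooled t statistics for every column of ``data``.

    ``data`` is (n_subjects, n_variables) with the first ``n_a`` rows being
    group A. Returns (t_obs shape (m,), t_perm shape (n_perm, m)); the same
    relabelings are applied to every column.
    """
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    n_b = n - n_a
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs n >= 2")
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in data")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tot = data.sum(axis=0)
    totsq = (data**2).sum(axis=0)
    sum_a = data[:n_a].sum(axis=0)
    sumsq_a = (data[:n_a] ** 2).sum(axis=0)
    t_obs = _pooled_t(sum_a, sumsq_a, n_a, tot - sum_a, totsq - sumsq_a, n_b)
    ind = _perm_indicator(n, n_a, n_perm, rng)
    psum_a = ind @ data
    psumsq_a = ind @ (data**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = _pooled_t(psum_a, psumsq_a, n_a, tot - psum_a, totsq - psumsq_a, n_b)
    return np.atleast_1d(t_obs), t_perm


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    metric: str = "",
    alpha: float = 0.05,
) -> GroupResult:
    """Two-sided permutation test on the pooled-variance two-sample t statistic.

    p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1), bounded below by
    1/(n_perm + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("zero pooled variance: test undefined")
    t_obs, t_perm = permutation_t_matrix(
        pooled[:, None], len(a), n_perm, seed
    )
    t_obs = float(t_obs[0])
    if not np.isfinite(t_obs):
        raise ValueError("observed t is not finite (zero within-group variance)")
    t_perm = t_perm[:, 0]
    t_perm = t_perm[np.isfinite(t_perm)]
    p = (1.0 + np.sum(np.abs(t_perm) >= abs(t_obs))) / (len(t_perm) + 1.0)
    return GroupResult(
        metric=metric,
        t_observed=t_obs,
        p_perm=float(p),
        n_permutations=int(n_perm),
        significant=bool(p < alpha),
        direction="decreased" if t_obs > 0 else "increased",
    )


def nodal_tests(
    enodal: np.ndarray,
    n_a: int,
    region_labels: list[str],
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[GroupResult]:
    """Per-region permutation tests on a (subjects x regions) nodal table.

    The first ``n_a`` rows are group A. Returns one GroupResult per region;
    ``significant`` flags the uncorrected permutation p < alpha, with the
    direction of the group-B change.
    """
    enodal = np.asarray(enodal, dtype=float)
    if enodal.shape[1] != len(region_labels):
        raise ValueError("one label per region column required")
    t_obs, t_perm = permutation_t_matrix(enodal, n_a, n_perm, seed)
    results = []
    for j, label in enumerate(region_labels):
        tp = t_perm[:, j]
        tp = tp[np.isfinite(tp)]
        p = (1.0 + np.sum(np.abs(tp) >= abs(t_obs[j]))) / (len(tp) + 1.0)
        results.append(
            GroupResult(
                metric=label,
                t_observed=float(t_obs[j]),
                p_perm=float(p),
                n_permutations=int(n_perm),
                significant=bool(p < alpha),
                direction="decreased" if t_obs[j] > 0 else "increased",
            )
        )
    return results


# ------------------------------------------------------------- edge level


def _edge_index(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_rois, k=1)


def edgewise_tests(
    z_edges: np.ndarray,
    n_a: int,
    region_labels: list[str],
    primary_p: float = 0.005,
    correction: str = "nbs",
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    component_stat: str = "size",
) -> list[EdgeFinding]:
    """Edge-wise group tests on pre-threshold Fisher-z connectivity.

    ``z_edges`` is (n_subjects, n_edges) holding the upper-triangle Fisher-z
    values in row-major (i < j) order; the first ``n_a`` rows are group A.

    correction="bonferroni": parametric two-sample t per edge; report edges
    whose Bonferroni-corrected p is below ``alpha``.

    correction="nbs": form the suprathreshold graph of edges with parametric
    p < ``primary_p``, extract its connected components, and assign each a
    family-wise p by comparing its statistic (edge count by default,
    "intensity" = sum of |t| optionally) with the maximal component
    statistic over ``n_perm`` relabelings. Components with p < alpha are
    reported (every member edge annotated with its component id).
    """
    z_edges = np.asarray(z_edges, dtype=float)
    n, n_edges = z_edges.shape
    n_rois = len(region_labels)
    iu, ju = _edge_index(n_rois)
    if n_edges != iu.size:
        raise ValueError(
            f"expected {iu.size} edge columns for {n_rois} regions, got {n_edges}"
        )
    n_b = n - n_a
    df = n - 2
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_crit = stats.t.isf(primary_p / 2.0, df)

    t_obs, t_perm = permutation_t_matrix(z_edges, n_a, n_perm, rng)
    p_param = 2.0 * stats.t.sf(np.abs(t_obs), df)

    def finding(j, p, comp=None):
        return EdgeFinding(
            region_i=region_labels[iu[j]],
            region_j=region_labels[ju[j]],
            t=float(t_obs[j]),
            p=float(p),
            direction="decreased" if t_obs[j] > 0 else "increased",
            component_id=comp,
        )

    if correction == "bonferroni":
        p_corr = np.minimum(p_param * n_edges, 1.0)
        return [finding(j, p_corr[j]) for j in np.flatnonzero(p_corr < alpha)]

    if correction != "nbs":
        raise ValueError("correction must be 'bonferroni' or 'nbs'")

    supra = np.flatnonzero(np.abs(t_obs) > t_crit)
    if supra.size == 0:
        return []
    adj = np.zeros((n_rois, n_rois), dtype=np.uint8)
    adj[iu[supra], ju[supra]] = 1
    adj |= adj.T
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    def comp_stat(edge_idx, t_vals):
        if component_stat == "intensity":
            return float(np.sum(np.abs(t_vals[edge_idx])))
        return float(edge_idx.size)

    # observed component statistics, indexed by component label
    comp_edges: dict[int, np.ndarray] = {}
    for j in supra:
        lbl = labels[iu[j]]
        comp_edges.setdefault(int(lbl), [])
        comp_edges[int(lbl)].append(j)
    comp_edges = {k: np.asarray(v) for k, v in comp_edges.items()}

    # permutation null of the maximal component statistic
    abs_tp = np.abs(t_perm)
    null_max = np.zeros(t_perm.shape[0])
    for p_idx in range(t_perm.shape[0]):
        sup = np.flatnonzero(abs_tp[p_idx] > t_crit)
        if sup.size == 0:
            continue
        a_p = np.zeros((n_rois, n_rois), dtype=np.uint8)
        a_p[iu[sup], ju[sup]] = 1
        a_p |= a_p.T
        _, lab_p = connected_components(csr_matrix(a_p), directed=False)
        best = 0.0
        for lbl in np.unique(lab_p[iu[sup]]):
            members = sup[lab_p[iu[sup]] == lbl]
            best = max(best, comp_stat(members, t_perm[p_idx]))
        null_max[p_idx] = best

    findings: list[EdgeFinding] = []
    for comp_id, (lbl, members) in enumerate(sorted(comp_edges.items())):
        s_obs = comp_stat(members, t_obs)
        p_comp = (1.0 + np.sum(null_max >= s_obs)) / (len(null_max) + 1.0)
        if p_comp < alpha:
            findings.extend(finding(j, p_comp, comp_id) for j in members)
    return findings


# ----------------------------------------------------------- regressions


def covariate_adjusted_correlation(
    metric: np.ndarray,
    behavior: np.ndarray,
    covariates: np.ndarray,
) -> tuple[float, float]:
    """Partial Pearson correlation of metric and behavior given covariates.

    Both variables are residualized on the covariates plus an intercept;
    the residual correlation r is tested with t = r sqrt(df / (1 - r^2)),
    df = n - K - 2 for K covariates.
    """
    y1 = np.asarray(metric, dtype=float)
    y2 = np.asarray(behavior, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim != 2:
        raise ValueError("covariates must be 2-D (n, K)")
    n, k = x.shape
    if y1.shape != (n,) or y2.shape != (n,):
        raise ValueError("metric/behavior must be length-n vectors")
    if n < k + 4:
        raise ValueError(f"need n >= {k + 4} observations, got {n}")
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta1, *_ = np.linalg.lstsq(design, y1, rcond=None)
    beta2, *_ = np.linalg.lstsq(design, y2, rcond=None)
    r1 = y1 - design @ beta1
    r2 = y2 - design @ beta2
    denom = np.sqrt((r1 @ r1) * (r2 @ r2))
    if denom == 0:
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float(np.clip((r1 @ r2) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)
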