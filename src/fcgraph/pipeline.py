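"""End-to-end orchestration: config, stage sequencing, result files.

A run executes: cohort simulation (or ingest of a directory of per-subject
TSV tables) -> nuisance regression and band-pass filtering -> per-subject
Fisher-z connectivity and the cost-threshold sweep -> graph metrics and
degree-preserving null normalization -> AUC summaries and permutation group
statistics -> result tables, a machine-readable report, and
BrainNetViewer-style export files.

Everything is a deterministic function of the RunConfig (including its
master seed); the report echoes the config and a hash of it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .atlas import synthetic_atlas
from .graphmetrics import global_metrics, nodal_metrics
from .groupstats import (
    covariate_adjusted_correlation,
    edgewise_tests,
    metric_auc,
    nodal_tests,
    permutation_test,
)
from .netbuild import DEFAULT_COST_GRID, pearson_fc, sweep
from .nullmodels import build_ensemble, small_world_indices
from .signalprep import RoiTimeSeries, bandpass_filter, regress_nuisance, synthetic_nuisance
from .synthdata import CohortSpec, simulate_cohort

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eglobal", "Elocal")
SW_METRIC_NAMES = ("gamma", "lambda", "sigma")


@dataclass
class RunConfig:
    """Serializable description of one full analysis run."""

    mode: str = "synthetic"  # or "directory"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None
    tr_seconds: float = 2.0
    cost_grid: list[float] = field(
        default_factory=lambda: [float(c) for c in DEFAULT_COST_GRID]
    )
    n_null_networks: int = 100
    n_permutations: int = 5000
    alpha: float = 0.05
    primary_p: float = 0.005
    correction: str = "nbs"
    regress_confounds: bool = True
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    seed: int = 0
    out_dir: str = "fcgraph_out"
    save_matrices: bool = False
    save_metric_tables: bool = True  # per-cost tidy tables can be bulky

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortSpec(**d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[list[RoiTimeSeries], pd.DataFrame]:
    if config.mode == "synthetic":
        records, covariates = simulate_cohort(config.cohort)
        return [r.timeseries for r in records], covariates
    if config.mode == "directory":
        if not config.input_dir:
            raise ValueError("directory mode requires input_dir")
        covariates = fio.read_covariates(Path(config.input_dir) / "covariates.tsv")
        # group A first, stable within group, so group-size bookkeeping is fixed
        covariates = covariates.sort_values(
            ["group", "subject_id"], kind="stable"
        ).reset_index(drop=True)
        series = fio.read_timeseries_dir(
            config.input_dir, covariates, config.tr_seconds
        )
        return series, covariates
    raise ValueError(f"unknown mode {config.mode!r}")


def preprocess_subject(
    ts: RoiTimeSeries, config: RunConfig, seed: int
) -> RoiTimeSeries:
    """Nuisance regression (synthetic 14-regressor set) then band-pass."""
    if config.regress_confounds:
        nuis = synthetic_nuisance(ts.n_timepoints, np.random.default_rng(seed))
        ts = regress_nuisance(ts, nuis)
    return bandpass_filter(ts, config.band_low_hz, config.band_high_hz)


def subject_metric_curves(
    ts: RoiTimeSeries,
    grid: np.ndarray,
    n_null: int,
    seed: int,
    compute_small_world: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Global and nodal metric values at every cost for one subject.

    Returns (global tidy frame, nodal tidy frame, Fisher-z upper triangle).
    The global frame has columns (subject_id, cost, metric, value) covering
    Cp/Lp/Eglobal/Elocal and, when ``compute_small_world``, gamma/lambda/
    sigma against ``n_null`` degree-preserving rewired networks.
    """
    cm = pearson_fc(ts)
    sw = sweep(cm, grid)
    iu, ju = np.triu_indices(cm.n_rois, k=1)
    z_upper = cm.z[iu, ju]
    grows = []
    nrows = []
    for k, net in enumerate(sw.networks):
        gm = global_metrics(net)
        for name in GLOBAL_METRIC_NAMES:
            grows.append((ts.subject_id, net.cost, name, getattr(gm, name)))
        if compute_small_world:
            ens = build_ensemble(
                net, n=n_null,
                seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31),
            )
            idx = small_world_indices(gm, ens)
            grows.append((ts.subject_id, net.cost, "gamma", idx.gamma))
            grows.append((ts.subject_id, net.cost, "lambda", idx.lam))
            grows.append((ts.subject_id, net.cost, "sigma", idx.sigma))
        nm = nodal_metrics(net, ts.region_labels)
        for lab, e in zip(ts.region_labels, nm.Enodal):
            nrows.append((ts.subject_id, net.cost, lab, e))
    gdf = pd.DataFrame(grows, columns=["subject_id", "cost", "metric", "value"])
    ndf = pd.DataFrame(nrows, columns=["subject_id", "cost", "region", "Enodal"])
    return gdf, ndf, z_upper


def auc_table(global_df: pd.DataFrame, grid: np.ndarray) -> pd.DataFrame:
    """Per-subject AUC of every metric curve over the full grid."""
    rows = []
    for (sid, name), g in global_df.groupby(["subject_id", "metric"], sort=False):
        g = g.sort_values("cost")
        if len(g) != len(grid) or not np.allclose(g["cost"].to_numpy(), grid):
            raise ValueError(
                f"metric {name} for {sid}: values missing for part of the grid"
            )
        rows.append((sid, name, metric_auc(g["value"].to_numpy(), grid)))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "auc"])


def small_world_screen(
    spec: CohortSpec,
    grid: np.ndarray | None = None,
    n_null: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject, per-cost small-world indices for a synthetic cohort.

    Simulates the cohort, builds Fisher-z matrices, thresholds them at every
    cost of the grid, and scores gamma, lambda and sigma against ``n_null``
    degree-preserving rewired networks each (no nuisance/filter stage: the
    generator's signals are already confound-free). Returns a tidy frame
    (subject_id, cost, Cp, Lp, gamma, lambda, sigma).
    """
    from .graphmetrics import characteristic_path_length, clustering_coefficient

    grid = DEFAULT_COST_GRID if grid is None else np.asarray(grid, dtype=float)
    records, _ = simulate_cohort(spec)
    rows = []
    for i, rec in enumerate(records):
        cm = pearson_fc(rec.timeseries)
        sw = sweep(cm, grid)
        for k, net in enumerate(sw.networks):
            _, cp = clustering_coefficient(net.adjacency)
            lp, _ = characteristic_path_length(net.adjacency)
            ens_seed = int(
                np.random.SeedSequence([seed, i, k]).generate_state(1)[0] % 2**31
            )
            ens = build_ensemble(net, n=n_null, seed=ens_seed)
            gamma = cp / ens.mean_Cp_rand
            lam = lp / ens.mean_Lp_rand
            rows.append((rec.subject_id, net.cost, cp, lp, gamma, lam,
                         gamma / lam))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "cost", "Cp", "Lp", "gamma", "lambda", "sigma"],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to disk).

    Output directory contents: ``covariates.tsv``, ``metrics_global.tsv``,
    ``metrics_nodal.tsv``, ``auc.tsv``, ``global_tests.tsv``,
    ``nodal_tests.tsv``, ``edge_findings.tsv``, ``report.json`` and
    BrainNetViewer ``findings.node``/``findings.edge``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = np.asarray(config.cost_grid, dtype=float)
    master = np.random.SeedSequence(config.seed)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    series, covariates = stage("ingest", _load_inputs, config)
    n_a = int((covariates["group"] == "A").sum())
    n_b = len(covariates) - n_a

    prepped = []
    for i, ts in enumerate(series):
        seed_i = int(np.random.SeedSequence([config.seed, 1, i]).generate_state(1)[0] % 2**31)
        try:
            prepped.append(preprocess_subject(ts, config, seed_i))
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'signalprep' failed for {ts.subject_id}: {exc}"
            ) from exc

    gframes, nframes, zrows = [], [], []
    for i, ts in enumerate(prepped):
        seed_i = int(np.random.SeedSequence([config.seed, 2, i]).generate_state(1)[0] % 2**31)
        try:
            gdf, ndf, z_upper = subject_metric_curves(
                ts, grid, config.n_null_networks, seed_i
            )
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage 'metrics' failed for {ts.subject_id}: {exc}"
            ) from exc
        gframes.append(gdf)
        nframes.append(ndf)
        zrows.append(z_upper)
        if config.save_matrices:
            cm = pearson_fc(ts)
            fio.write_matrix(cm.z, ts.region_labels,
                             out / "matrices" / f"{ts.subject_id}_z.tsv")
    global_df = pd.concat(gframes, ignore_index=True)
    nodal_df = pd.concat(nframes, ignore_index=True)
    z_edges = np.vstack(zrows)
    region_labels = prepped[0].region_labels

    aucs = stage("auc", auc_table, global_df, grid)

    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_group_a": n_a,
        "n_group_b": n_b,
        "region_labels": list(region_labels),
        "global_tests": [],
        "nodal_tests": [],
        "edge_findings": [],
        "behavior_correlations": [],
    }

    gtests_rows, ntests_rows, efind_rows = [], [], []
    if min(n_a, n_b) >= 2:
        seed_stats = int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % 2**31)
        wide = aucs.pivot(index="subject_id", columns="metric", values="auc")
        wide = wide.loc[covariates["subject_id"]]  # group A rows first
        for m_idx, name in enumerate(list(GLOBAL_METRIC_NAMES) + list(SW_METRIC_NAMES)):
            if name not in wide.columns:
                continue
            vals = wide[name].to_numpy()
            res = stage(
                "groupstats", permutation_test,
                vals[:n_a], vals[n_a:], config.n_permutations,
                np.random.default_rng([seed_stats, 10 + m_idx]),
                name, config.alpha,
            )
            report["global_tests"].append(dataclasses.asdict(res))
            gtests_rows.append((name, res.t_observed, res.p_perm,
                                res.n_permutations, res.significant, res.direction))

        # nodal tests on Enodal AUC
        nodal_auc = (
            nodal_df.groupby(["subject_id", "region"], sort=False)
            .apply(lambda g: metric_auc(
                g.sort_values("cost")["Enodal"].to_numpy(), grid),
                include_groups=False)
            .unstack("region")
            .loc[covariates["subject_id"], region_labels]
        )
        nres = stage(
            "groupstats", nodal_tests, nodal_auc.to_numpy(), n_a,
            region_labels, config.n_permutations, config.alpha,
            np.random.default_rng([seed_stats, 1]),
        )
        for r in nres:
            if r.significant:
                report["nodal_tests"].append(dataclasses.asdict(r))
            ntests_rows.append((r.metric, r.t_observed, r.p_perm, r.significant,
                                r.direction))

        findings = stage(
            "groupstats", edgewise_tests, z_edges, n_a, region_labels,
            config.primary_p, config.correction, config.alpha,
            config.n_permutations, np.random.default_rng([seed_stats, 2]),
        )
        for f in findings:
            report["edge_findings"].append(dataclasses.asdict(f))
            efind_rows.append((f.region_i, f.region_j, f.t, f.p, f.direction,
                               f.component_id))

        # brain-behavior: metric AUC vs duration within group B,
        # controlling age and education
        is_b = (covariates["group"] == "B").to_numpy()
        duration = covariates.loc[is_b, "duration_years"].to_numpy(dtype=float)
        if duration.size >= 6 and np.all(np.isfinite(duration)):
            covs = covariates.loc[
                is_b, ["age_years", "education_years"]
            ].to_numpy(dtype=float)
            for name in ("Cp", "Elocal"):
                vals = wide[name].to_numpy()[n_a:]
                r, p = stage(
                    "groupstats", covariate_adjusted_correlation,
                    vals, duration, covs,
                )
                report["behavior_correlations"].append(
                    dict(metric=name, behavior="duration_years",
                         partial_r=r, p=p)
                )
    else:
        logger.info("single-group run: group statistics skipped")

    # ------------------------------------------------------------- outputs
    fio.write_covariates(covariates, out / "covariates.tsv")
    if config.save_metric_tables:
        global_df.to_csv(out / "metrics_global.tsv", sep="\t", index=False,
                         float_format=fio.FLOAT_FMT)
        nodal_df.to_csv(out / "metrics_nodal.tsv", sep="\t", index=False,
                        float_format=fio.FLOAT_FMT)
    aucs.to_csv(out / "auc.tsv", sep="\t", index=False,
                float_format=fio.FLOAT_FMT)
    pd.DataFrame(
        gtests_rows,
        columns=["metric", "t", "p_perm", "n_perm", "significant", "direction"],
    ).to_csv(out / "global_tests.tsv", sep="\t", index=False)
    pd.DataFrame(
        ntests_rows, columns=["region", "t", "p_perm", "significant", "direction"]
    ).to_csv(out / "nodal_tests.tsv", sep="\t", index=False)
    pd.DataFrame(
        efind_rows,
        columns=["region_i", "region_j", "t", "p", "direction", "component_id"],
    ).to_csv(out / "edge_findings.tsv", sep="\t", index=False)

    atlas = synthetic_atlas(len(region_labels))
    atlas = atlas.assign(label=region_labels)  # node order = data order
    from .groupstats import EdgeFinding

    findings_objs = [
        EdgeFinding(*row) for row in efind_rows
    ]
    nodal_scores = {
        row[0]: abs(row[1]) for row in ntests_rows if row[3]
    }
    fio.export_brainnetviewer(
        findings_objs, nodal_scores, atlas,
        out / "findings.node", out / "findings.edge",
    )
    fio.write_json(report, out / "report.json")
    return report
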