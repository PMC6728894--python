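"""Strict TSV reading/writing for every on-disk artifact of the pipeline.

One dialect throughout: tab separator, dot decimal, one header row, floats
written with 17 significant digits so write -> read round-trips are
lossless for doubles. Validation errors carry file names and line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signalprep import RoiTimeSeries

FLOAT_FMT = "%.17g"


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> Path:
    """Write one subject's T x N signal table (header = region labels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(ts.region_labels)
    np.savetxt(path, ts.values, fmt=FLOAT_FMT, delimiter="\t",
               header=header, comments="")
    return path


def read_timeseries(
    path: str | Path, tr_seconds: float, subject_id: str | None = None
) -> RoiTimeSeries:
    """Read a subject signal table, validating shape row by row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing subject time-series file: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        n = len(labels)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n:
                raise ValueError(
                    f"{path}:{lineno}: expected {n} fields, got {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return RoiTimeSeries(
        subject_id or path.stem, np.asarray(rows), tr_seconds, labels
    )


def read_timeseries_dir(
    directory: str | Path, covariates: pd.DataFrame, tr_seconds: float
) -> list[RoiTimeSeries]:
    """Read `<subject_id>.tsv` for every covariates row; label orders must agree."""
    directory = Path(directory)
    out: list[RoiTimeSeries] = []
    ref_labels: list[str] | None = None
    ref_file: Path | None = None
    for sid in covariates["subject_id"]:
        f = directory / f"{sid}.tsv"
        ts = read_timeseries(f, tr_seconds, subject_id=sid)
        if ref_labels is None:
            ref_labels, ref_file = ts.region_labels, f
        elif ts.region_labels != ref_labels:
            raise ValueError(
                f"region-label order mismatch between {ref_file} and {f}"
            )
        out.append(ts)
    return out


def write_matrix(
    matrix: np.ndarray, labels: list[str], path: str | Path
) -> Path:
    """Write a square labelled matrix (header row + leading label column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join([""] + labels) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")[1:]
        n = len(labels)
        m = np.empty((n, n))
        for i, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n + 1:
                raise ValueError(f"{path}:{i + 2}: expected {n + 1} fields")
            m[i] = [float(f) for f in fields[1:]]
    return m, labels


def write_covariates(cov: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cov.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing covariates table: {path}")
    cov = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"subject_id", "group"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return cov


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def export_brainnetviewer(
    findings,
    nodal_scores: dict[str, float],
    atlas: pd.DataFrame,
    node_path: str | Path,
    edge_path: str | Path,
) -> tuple[Path, Path]:
    """Write BrainNetViewer-style .node and .edge text files.

    .node: one row per region, whitespace-separated
    ``x y z color_group size label`` (size = the region's nodal score, 0 if
    absent; color group 2 for scored regions, 1 otherwise).
    .edge: the full N x N matrix of signed t values for reported edges,
    zero elsewhere.
    """
    from .atlas import validate_atlas

    validate_atlas(atlas)
    labels = list(atlas["label"])
    index = {lab: i for i, lab in enumerate(labels)}
    for lab in nodal_scores:
        if lab not in index:
            raise ValueError(f"unknown region label in nodal scores: {lab}")
    node_path, edge_path = Path(node_path), Path(edge_path)
    node_path.parent.mkdir(parents=True, exist_ok=True)
    with open(node_path, "w") as fh:
        for _, row in atlas.iterrows():
            score = nodal_scores.get(row["label"], 0.0)
            color = 2 if row["label"] in nodal_scores else 1
            fh.write(
                f"{row['x']:g} {row['y']:g} {row['z']:g} "
                f"{color:d} {score:.6g} {row['label']}\n"
            )
    n = len(labels)
    mat = np.zeros((n, n))
    for f in findings:
        if f.region_i not in index or f.region_j not in index:
            raise ValueError(
                f"unknown region label in finding: {f.region_i}-{f.region_j}"
            )
        i, j = index[f.region_i], index[f.region_j]
        mat[i, j] = mat[j, i] = f.t
    with open(edge_path, "w") as fh:
        for row in mat:
            fh.write(" ".join("%.6g" % v for v in row) + "\n")
    return node_path, edge_path
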