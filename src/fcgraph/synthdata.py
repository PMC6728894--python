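"""Synthetic two-group cohorts of parcellated ROI time series.

Emulates a resting-state fMRI case/control study design: group A
("nonsmoker-like" controls) and group B ("smoker-like" cases), each subject
a T x N table of band-limited signals with a modular, small-world-generating
correlation structure. Group B carries a tunable deficit in within-module
correlation — which propagates downstream to lower clustering and local
efficiency — plus an optional per-subject attenuation proportional to a
smoking-duration covariate, so a planted metric-duration association is
recoverable by the real analysis pipeline.

Everything is a pure function of the :class:`CohortSpec`, including its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .signalprep import RoiTimeSeries

logger = logging.getLogger(__name__)

# Eigenvalues of a proposed correlation matrix below this are a hard error;
# in [_PSD_TOL, 0) they are clipped to zero (and the repair logged).
_PSD_TOL = -1e-10


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; the seed makes it reproducible.

    Defaults mirror the emulated study design: 32 controls vs 30 cases,
    246 regions, 170 retained volumes at TR = 2 s, and a 6-module
    correlation structure (0.35 within-module, 0.05 between).
    ``clustering_deficit`` scales down group B's within-module correlation;
    ``duration_effect`` adds a further per-subject attenuation proportional
    to the smoking-duration covariate (years).
    """

    n_group_a: int = 32
    n_group_b: int = 30
    n_rois: int = 246
    n_timepoints: int = 170
    tr_seconds: float = 2.0
    n_modules: int = 6
    within_module_corr: float = 0.35
    between_module_corr: float = 0.05
    clustering_deficit: float = 0.0
    duration_effect: float = 0.0
    noise_sd: float = 0.5
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b) < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_rois < 2 or self.n_modules < 1 or self.n_modules > self.n_rois:
            raise ValueError("need 2 <= n_modules <= n_rois")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if not 0 <= self.within_module_corr < 1:
            raise ValueError("within_module_corr must be in [0, 1)")
        if not 0 <= self.between_module_corr < self.within_module_corr:
            raise ValueError(
                "need 0 <= between_module_corr < within_module_corr "
                "(otherwise there is no modular structure)"
            )
        if not 0 <= self.clustering_deficit < 1:
            raise ValueError("clustering_deficit must be in [0, 1)")
        if self.duration_effect < 0:
            raise ValueError("duration_effect must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    """One simulated subject: covariates plus the raw signal table."""

    subject_id: str
    group: str  # "A" (control-like) or "B" (case-like)
    age_years: float
    education_years: float
    duration_years: float  # NaN for group A
    timeseries: RoiTimeSeries


def module_partition(n_rois: int, n_modules: int) -> np.ndarray:
    """Near-equal contiguous module labels; the remainder goes to the last module."""
    size = n_rois // n_modules
    labels = np.repeat(np.arange(n_modules), size)
    if labels.size < n_rois:  # remainder
        labels = np.concatenate(
            [labels, np.full(n_rois - labels.size, n_modules - 1)]
        )
    return labels


def _psd_repair(cov: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues to zero; hard error below tolerance."""
    w = np.linalg.eigvalsh(cov)
    w_min = w.min()
    if w_min >= 0:
        return cov
    if w_min < _PSD_TOL:
        raise ValueError(
            f"covariance is not positive semi-definite: eigenvalue {w_min:.3e} "
            f"below tolerance {_PSD_TOL:.0e}"
        )
    logger.warning("PSD repair: clipping eigenvalue %.3e to 0", w_min)
    w_full, v = np.linalg.eigh(cov)
    w_full = np.clip(w_full, 0.0, None)
    return (v * w_full) @ v.T


def build_group_covariance(
    spec: CohortSpec, group: str, duration: float | None = None
) -> np.ndarray:
    """Block-structured correlation matrix for one subject's signal component.

    Within-module entries are ``within_module_corr``; for group B they are
    scaled by ``(1 - clustering_deficit)`` and further by
    ``(1 - duration_effect * duration)`` (floored so the modular ordering
    within > between is never inverted). Between-module entries are
    ``between_module_corr``; diagonal is 1.
    """
    if group not in ("A", "B"):
        raise ValueError(f"unknown group {group!r}")
    within = spec.within_module_corr
    if group == "B":
        within *= 1.0 - spec.clustering_deficit
        if duration is not None and np.isfinite(duration):
            within *= max(0.0, 1.0 - spec.duration_effect * duration)
        within = max(within, spec.between_module_corr)
    labels = module_partition(spec.n_rois, spec.n_modules)
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, within, spec.between_module_corr)
    np.fill_diagonal(cov, 1.0)
    return _psd_repair(cov)


def simulate_subject(
    cov: np.ndarray,
    n_timepoints: int,
    noise_sd: float,
    seed: int | np.random.Generator,
    ar1: float = 0.0,
) -> np.ndarray:
    """Draw a column-standardized T x N signal table with signal covariance ``cov``.

    Factor construction: the symmetric square root of ``cov`` mixes iid
    standard-normal innovations (optionally AR(1)-smoothed with coefficient
    ``ar1``); iid measurement noise with standard deviation ``noise_sd`` is
    added, and each column is z-scored. For standardized outputs the
    realized signal correlation is attenuated to ``cov / (1 + noise_sd**2)``
    off the diagonal, in expectation.
    """
    if n_timepoints < 3:
        raise ValueError("need at least 3 time points (correlation undefined below)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    w, v = np.linalg.eigh(cov)
    if w.min() < _PSD_TOL:
        raise ValueError(f"covariance not PSD: eigenvalue {w.min():.3e}")
    root = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n_timepoints, n))
    if ar1 > 0.0:
        from scipy.signal import lfilter

        z = lfilter([np.sqrt(1.0 - ar1**2)], [1.0, -ar1], z, axis=0)
    x = z @ root.T
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((n_timepoints, n))
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate (zero-variance) simulated column")
    return x / sd


# Group-B smoking duration: lognormal with median 4.5 years, log-sd 0.45
# (sd ~ 2.4 y). Ages ~ N(21, 1.1), education ~ N(14.1, 0.55), both groups.
_DURATION_MEDIAN = 4.5
_DURATION_LOG_SD = 0.45
_AGE_MEAN, _AGE_SD = 21.0, 1.1
_EDU_MEAN, _EDU_SD = 14.1, 0.55


def simulate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate every subject in the cohort.

    Returns the subject records (group A first) and a covariates table with
    columns subject_id, group, age_years, education_years, duration_years,
    seed. Ages and education are drawn from the same distribution in both
    groups (matched by construction).
    """
    n_total = spec.n_group_a + spec.n_group_b
    region_labels = [f"ROI_{i + 1:03d}" for i in range(spec.n_rois)]
    records: list[SubjectRecord] = []
    rows = []
    for idx in range(n_total):
        group = "A" if idx < spec.n_group_a else "B"
        ss = np.random.SeedSequence([spec.seed, idx])
        subject_seed = int(ss.generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(ss)
        age = rng.normal(_AGE_MEAN, _AGE_SD)
        edu = rng.normal(_EDU_MEAN, _EDU_SD)
        if group == "B":
            duration = float(
                np.exp(rng.normal(np.log(_DURATION_MEDIAN), _DURATION_LOG_SD))
            )
        else:
            duration = float("nan")
        cov = build_group_covariance(spec, group, duration if group == "B" else None)
        values = simulate_subject(
            cov, spec.n_timepoints, spec.noise_sd, rng, ar1=spec.ar1
        )
        sid = f"sub-{group}{(idx if group == 'A' else idx - spec.n_group_a) + 1:02d}"
        ts = RoiTimeSeries(sid, values, spec.tr_seconds, list(region_labels))
        records.append(SubjectRecord(sid, group, age, edu, duration, ts))
        rows.append(
            dict(subject_id=sid, group=group, age_years=age,
                 education_years=edu, duration_years=duration,
                 seed=subject_seed)
        )
    covariates = pd.DataFrame(rows)
    return records, covariates
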