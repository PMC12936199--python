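"""Unsupervised clustering of longitudinal ctDNA trajectories.

Each patient is represented as a univariate series of transformed ctDNA
levels, ``log10(ppm + 1)`` with undetected timepoints at 0. Timelines are
irregularly sampled and unequal in length, so the pairwise distance is
dynamic time warping (absolute-difference local cost, full window); the
distance matrix feeds average-linkage (UPGMA) agglomerative clustering cut
at k = 2. The two clusters are labelled high-/low-risk from ctDNA features
alone (median baseline level, clearance fraction as tie-break) — never
from survival or response data. A sensitivity variant re-runs the pipeline
after reclassifying sub-100-PPM calls as undetected, probing how much of
the group structure lives in the ultrasensitive range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering

from .detect import apply_detection_floor

__all__ = [
    "TrajectorySeries",
    "ClusterAssignment",
    "ts_distance",
    "dtw_distance",
    "series_from_calls",
    "cluster_patients",
    "label_risk",
    "sensitivity_recluster",
    "TrajectoryClusterer",
]

MIN_SERIES_LEN = 2


@dataclass(frozen=True)
class TrajectorySeries:
    """One patient's transformed ctDNA level series."""

    patient_id: str
    days: tuple[float, ...]
    values: tuple[float, ...]  # log10(ppm + 1); 0 where undetected

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValueError("days and values must have equal length")
        if not all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")


@dataclass(frozen=True)
class ClusterAssignment:
    patient_id: str
    cluster_index: int
    risk_label: str | None = None  # "high" | "low"


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic time warping distance with |.| local cost and full window.

    Classic O(len(a) * len(b)) recurrence; symmetric, zero on identical
    series, handles unequal lengths.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n < MIN_SERIES_LEN or m < MIN_SERIES_LEN:
        raise ValueError("DTW requires series of length >= 2")
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        for j in range(1, m):
            acc[i, j] = cost[i, j] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    return float(acc[n - 1, m - 1])


def _interp_euclidean(a_days, a_vals, b_days, b_vals, n_grid: int = 25) -> float:
    """Euclidean distance after linear interpolation onto a common day grid.

    Robustness alternative to DTW.
    """
    lo = max(min(a_days), min(b_days))
    hi = min(max(a_days), max(b_days))
    if hi <= lo:  # no overlap: fall back to comparing means
        return abs(float(np.mean(a_vals)) - float(np.mean(b_vals)))
    grid = np.linspace(lo, hi, n_grid)
    ai = np.interp(grid, a_days, a_vals)
    bi = np.interp(grid, b_days, b_vals)
    return float(np.sqrt(np.mean((ai - bi) ** 2)))


def ts_distance(a: TrajectorySeries, b: TrajectorySeries, metric: str = "dtw") -> float:
    """Distance between two patient trajectories."""
    if metric == "dtw":
        return dtw_distance(np.asarray(a.values), np.asarray(b.values))
    if metric == "interp_euclidean":
        if len(a.values) < MIN_SERIES_LEN or len(b.values) < MIN_SERIES_LEN:
            raise ValueError("series must have length >= 2")
        return _interp_euclidean(a.days, a.values, b.days, b.values)
    raise ValueError(f"unknown metric {metric!r}")


def series_from_calls(calls: pd.DataFrame, min_len: int = MIN_SERIES_LEN) -> list[TrajectorySeries]:
    """Build per-patient transformed series from a calls table.

    Patients with fewer than ``min_len`` samples are excluded (they carry
    no dynamic information).
    """
    out = []
    for pid, grp in calls.groupby("patient_id", sort=True):
        grp = grp.sort_values("sample_day")
        if len(grp) < min_len:
            continue
        vals = np.log10(grp["ppm"].to_numpy(dtype=float) + 1.0)
        out.append(
            TrajectorySeries(
                patient_id=pid,
                days=tuple(float(d) for d in grp["sample_day"]),
                values=tuple(float(v) for v in vals),
            )
        )
    return out


class TrajectoryClusterer(BaseEstimator, ClusterMixin):
    """Agglomerative clustering of ctDNA trajectories under a DTW metric.

    Parameters
    ----------
    n_clusters : int, default 2
        Number of dynamic groups; the high/low risk labelling is defined
        for 2.
    metric : {"dtw", "interp_euclidean"}, default "dtw"
        Trajectory distance.
    linkage : str, default "average"
        UPGMA by default — Ward assumes Euclidean geometry DTW lacks.

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of cluster indices, one per series.
    distance_matrix_ : condensed-to-square pairwise distance matrix.
    risk_labels_ : list of "high"/"low" per series (only for n_clusters=2).
    degenerate_ : True when all pairwise distances are ~0 (single
        effective cluster reported as all-zero labels).
    """

    def __init__(self, n_clusters: int = 2, metric: str = "dtw", linkage: str = "average"):
        self.n_clusters = n_clusters
        self.metric = metric
        self.linkage = linkage

    def fit(self, X: list[TrajectorySeries], y=None) -> "TrajectoryClusterer":
        if len(X) < 2 * self.n_clusters:
            raise ValueError(
                f"need at least {2 * self.n_clusters} series for k={self.n_clusters}"
            )
        n = len(X)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = ts_distance(X[i], X[j], self.metric)
        self.distance_matrix_ = D
        self.series_ids_ = [s.patient_id for s in X]
        if np.allclose(D, 0.0):
            self.degenerate_ = True
            self.labels_ = np.zeros(n, dtype=int)
        else:
            self.degenerate_ = False
            model = AgglomerativeClustering(
                n_clusters=self.n_clusters, metric="precomputed", linkage=self.linkage
            )
            self.labels_ = model.fit_predict(D)
        if self.n_clusters == 2 and not self.degenerate_:
            self.risk_labels_ = _risk_labels(self.labels_, X)
        else:
            self.risk_labels_ = [None] * n
        return self

    def fit_predict(self, X: list[TrajectorySeries], y=None) -> np.ndarray:
        return self.fit(X).labels_

    def assignments_(self) -> list[ClusterAssignment]:
        return [
            ClusterAssignment(pid, int(c), r)
            for pid, c, r in zip(self.series_ids_, self.labels_, self.risk_labels_)
        ]


def _risk_labels(labels: np.ndarray, series: list[TrajectorySeries]) -> list[str]:
    """Outcome-free high/low risk labelling of a 2-way partition.

    High risk = cluster with the greater median baseline (first-sample)
    level; ties broken by the lower clearance fraction (fraction of
    patients whose series ever reaches 0).
    """
    stats = {}
    for c in (0, 1):
        members = [s for s, l in zip(series, labels) if l == c]
        baselines = [s.values[0] for s in members]
        cleared = [float(min(s.values) == 0.0) for s in members]
        stats[c] = (float(np.median(baselines)), float(np.mean(cleared)))
    b0, cl0 = stats[0]
    b1, cl1 = stats[1]
    if b0 != b1:
        high = 0 if b0 > b1 else 1
    elif cl0 != cl1:
        high = 0 if cl0 < cl1 else 1
    else:
        high = 0  # fully tied partitions are arbitrary; pick deterministically
    return ["high" if l == high else "low" for l in labels]


def cluster_patients(
    series: list[TrajectorySeries], k: int = 2, metric: str = "dtw"
) -> list[ClusterAssignment]:
    """Cluster patient trajectories; thin wrapper over TrajectoryClusterer."""
    model = TrajectoryClusterer(n_clusters=k, metric=metric).fit(series)
    return model.assignments_()


def label_risk(
    assignments: list[ClusterAssignment], series: list[TrajectorySeries]
) -> list[ClusterAssignment]:
    """Attach high/low risk labels to a 2-cluster assignment."""
    clusters = {a.cluster_index for a in assignments}
    if clusters - {0, 1} or len(clusters) > 2:
        raise ValueError("risk labelling is defined for exactly 2 clusters")
    by_id = {s.patient_id: s for s in series}
    ordered = [by_id[a.patient_id] for a in assignments]
    labels = np.array([a.cluster_index for a in assignments])
    risks = _risk_labels(labels, ordered)
    return [
        ClusterAssignment(a.patient_id, a.cluster_index, r)
        for a, r in zip(assignments, risks)
    ]


def sensitivity_recluster(
    calls: pd.DataFrame,
    floor_ppm: float = 100.0,
    k: int = 2,
    metric: str = "dtw",
    survival: pd.DataFrame | None = None,
) -> dict:
    """Re-run clustering after flooring sub-threshold calls to undetected.

    Returns a dict with the floored ``assignments`` (and the model), plus
    the between-cluster log-rank p for PFS when a clinical table with
    ``pfs_days``/``pfs_event`` is supplied and the partition is
    non-degenerate.
    """
    floored = apply_detection_floor(calls, floor_ppm)
    series = series_from_calls(floored)
    model = TrajectoryClusterer(n_clusters=k, metric=metric).fit(series)
    out = {"assignments": model.assignments_(), "model": model, "degenerate": model.degenerate_}
    if survival is not None and not model.degenerate_:
        from .survstats import logrank_test

        assign = pd.DataFrame(
            {"patient_id": model.series_ids_, "cluster": model.labels_}
        )
        merged = assign.merge(survival, on="patient_id")
        if merged["cluster"].nunique() == 2:
            res = logrank_test(
                merged["pfs_days"].to_numpy(),
                merged["pfs_event"].to_numpy(),
                merged["cluster"].to_numpy(),
            )
            out["logrank_p"] = res.p_value
    return out
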