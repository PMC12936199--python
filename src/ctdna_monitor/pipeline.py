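"""End-to-end orchestration: simulate -> detect -> classify -> cluster -> survival.

Stages communicate only through the TSV tables in the output directory, so
each is individually invokable and re-runnable. Every run writes a
``summary.txt`` report (mR-by-BOR table, hazard ratios, lead times,
cluster outcomes, 100-PPM floor sensitivity) and records the config hash
that produced it.
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

from . import io as cio
from .cluster import TrajectoryClusterer, sensitivity_recluster, series_from_calls
from .detect import PoissonDetector
from .response import MolecularResponseLabeler
from .simulate import AssayConfig, simulate_cohort
from .survstats import cox_fit, fisher_exact_rxc, km_estimate, logrank_test

logger = logging.getLogger("ctdna_monitor")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run."""

    seed: int = 0
    n_patients: int = 39
    alpha: float = 0.001
    lod_power: float = 0.95
    mr_thresholds: tuple[float, ...] = (0.3, 0.5, 0.75)
    mpd_increase: float = 0.3
    followup_window: tuple[float, float] = (10.0, 45.0)
    floor_ppm: float = 100.0  # sensitivity-analysis floor
    cluster_k: int = 2
    cluster_metric: str = "dtw"
    out_dir: str = "ctdna_run"
    simulate: bool = True
    input_dir: str | None = None  # read measurements/clinical here if not simulating

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _survival_row(exposure, endpoint, result):
    return {
        "exposure": exposure,
        "endpoint": endpoint,
        "hr": result.hazard_ratio,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "p": result.p_value,
        "n": result.n,
    }


def _binary_cox(merged: pd.DataFrame, flag_col: str, time_col: str, event_col: str):
    sub = merged.dropna(subset=[flag_col, time_col, event_col])
    cov = pd.DataFrame({flag_col: sub[flag_col].astype(float)})
    if cov[flag_col].nunique() < 2 or sub[event_col].sum() < 1:
        return None
    return cox_fit(cov, sub[time_col], sub[event_col])[0]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        logger.info("simulating cohort: n=%d seed=%d", config.n_patients, config.seed)
        measurements, clinical = simulate_cohort(
            config.n_patients, assay=AssayConfig(), seed=config.seed
        )
    else:
        src = Path(config.input_dir or out)
        measurements = cio.read_table(src / "measurements.tsv", "measurements")
        clinical = cio.read_table(src / "clinical.tsv", "clinical")
    cio.write_table(measurements, out / "measurements.tsv")
    cio.write_table(clinical, out / "clinical.tsv")
    logger.info(
        "inputs: %d patients, %d samples", clinical["patient_id"].nunique(), len(measurements)
    )

    # --- detection --------------------------------------------------------
    detector = PoissonDetector(alpha=config.alpha, power=config.lod_power)
    calls = detector.fit(measurements).transform(measurements)
    cio.write_table(calls, out / "calls.tsv")
    det = calls[calls["detected"]]
    frac_below_100 = float((det["ppm"] < 100).mean()) if len(det) else float("nan")
    logger.info(
        "detection: %d/%d samples positive, %.0f%% below 100 PPM",
        len(det), len(calls), 100 * frac_below_100,
    )

    # --- molecular response labels ---------------------------------------
    labeler = MolecularResponseLabeler(
        mr_thresholds=config.mr_thresholds,
        mpd_increase=config.mpd_increase,
        followup_window=config.followup_window,
    )
    labels = labeler.fit(calls).transform(calls, clinical)
    cio.write_table(labels, out / "labels.tsv")
    evaluable = labels[labels["mr_50"] != "not_evaluable"]
    logger.info("mR evaluable: %d/%d patients", len(evaluable), len(labels))

    # --- clustering -------------------------------------------------------
    series = series_from_calls(calls)
    clusters = None
    if len(series) >= 2 * config.cluster_k:
        model = TrajectoryClusterer(
            n_clusters=config.cluster_k, metric=config.cluster_metric
        ).fit(series)
        clusters = pd.DataFrame(
            {
                "patient_id": model.series_ids_,
                "cluster": model.labels_,
                "risk_label": model.risk_labels_,
            }
        )
        cio.write_table(clusters, out / "clusters.tsv")
    spider = calls[["patient_id", "sample_day"]].copy()
    spider["log10_ppm_plus1"] = np.log10(calls["ppm"] + 1.0)
    cio.write_table(spider, out / "spider_data.tsv")

    # --- survival / association statistics -------------------------------
    merged = labels.merge(clinical, on="patient_id")
    merged["mr50_flag"] = merged["mr_50"].map({"response": 1.0, "no_response": 0.0})
    merged["mcr_flag"] = merged["mcr"].astype(float)
    merged["mpd_flag"] = (merged["n_mpd_timepoints"] > 0).astype(float)

    rows, report = [], {}
    for exposure, flag in (("mr_50", "mr50_flag"), ("mcr", "mcr_flag"), ("mpd", "mpd_flag")):
        for endpoint, tcol, ecol in (("pfs", "pfs_days", "pfs_event"), ("os", "os_days", "os_event")):
            res = _binary_cox(merged, flag, tcol, ecol)
            if res is not None:
                rows.append(_survival_row(exposure, endpoint, res))

    # multivariable Cox: mR + TMB (>=10 mut/Mb) + MSI-H, PFS
    mv = merged.dropna(subset=["mr50_flag"]).copy()
    mv["tmb_high"] = (mv["tmb"] >= 10).astype(float)
    mv["msi_h"] = (mv["msi"] == "MSI-H").astype(float)
    mv_cols = [c for c in ("mr50_flag", "tmb_high", "msi_h") if mv[c].nunique() > 1]
    if len(mv) >= 10 and "mr50_flag" in mv_cols and mv["pfs_event"].sum() >= 3:
        for res in cox_fit(mv[mv_cols], mv["pfs_days"], mv["pfs_event"]):
            rows.append(_survival_row(f"multivariable:{res.covariate}", "pfs", res))

    # cluster risk vs survival
    if clusters is not None and clusters["risk_label"].nunique() == 2:
        cm = clusters.merge(clinical, on="patient_id")
        cm["high_risk"] = (cm["risk_label"] == "high").astype(float)
        for endpoint, tcol, ecol in (("pfs", "pfs_days", "pfs_event"), ("os", "os_days", "os_event")):
            res = _binary_cox(cm, "high_risk", tcol, ecol)
            if res is not None:
                rows.append(_survival_row("high_risk_cluster", endpoint, res))

    survival_report = pd.DataFrame(rows)
    cio.write_table(survival_report, out / "survival_report.tsv")

    # mR x BOR association (Freeman–Halton exact test)
    tab = None
    assoc = evaluable.merge(clinical, on="patient_id")
    assoc = assoc[assoc["bor"].isin(["PR", "SD", "PD"])]
    if len(assoc) and assoc["mr_50"].nunique() == 2:
        tab = pd.crosstab(assoc["mr_50"], assoc["bor"]).reindex(
            index=["response", "no_response"], columns=["PR", "SD", "PD"], fill_value=0
        )
        report["fisher_mr_bor_p"] = fisher_exact_rxc(tab.to_numpy())

    # lead time + mPD counts
    lead = merged["lead_time_days"].dropna()
    report["n_mpd_timepoints"] = int(merged["n_mpd_timepoints"].sum())
    report["median_lead_time_days"] = float(lead.median()) if len(lead) else None

    # 1-year PFS by mCR (KM)
    for flag, name in ((1, "mcr"), (0, "non_mcr")):
        sub = merged[merged["mcr_flag"] == flag]
        if len(sub):
            report[f"pfs_1y_{name}"] = km_estimate(
                sub["pfs_days"], sub["pfs_event"]
            ).survival_at(365.0)

    # 100 PPM floor sensitivity re-clustering
    sens = None
    if len(series) >= 2 * config.cluster_k:
        sens = sensitivity_recluster(
            calls, floor_ppm=config.floor_ppm, k=config.cluster_k,
            metric=config.cluster_metric, survival=clinical,
        )
        report["floor_sensitivity_degenerate"] = sens["degenerate"]
        if "logrank_p" in sens:
            report["floor_sensitivity_logrank_p"] = sens["logrank_p"]

    report["frac_detections_below_100ppm"] = frac_below_100
    report["median_lod_ppm"] = float(calls["lod_ppm"].median())
    report["config_hash"] = config.config_hash()

    _write_summary(out / "summary.txt", config, report, tab, survival_report)
    return {
        "calls": calls,
        "labels": labels,
        "clusters": clusters,
        "survival_report": survival_report,
        "report": report,
        "mr_bor_table": tab,
        "sensitivity": sens,
    }


def _write_summary(path: Path, config: RunConfig, report: dict, tab, survival_report) -> None:
    lines = [
        "ctDNA monitoring pipeline summary",
        f"config hash: {report['config_hash']}",
        "",
        f"median per-sample LOD: {report['median_lod_ppm']:.2f} PPM",
        f"fraction of detections < 100 PPM: {100 * report['frac_detections_below_100ppm']:.1f}%",
        "",
    ]
    if tab is not None:
        lines += ["mR (50%) by best overall response:", tab.to_string(),
                  f"Freeman–Halton exact p = {report['fisher_mr_bor_p']:.4f}", ""]
    if len(survival_report):
        lines += ["survival analyses:", survival_report.to_string(index=False), ""]
    if report.get("median_lead_time_days") is not None:
        lines.append(f"median mPD lead time: {report['median_lead_time_days']:.1f} days")
    lines.append(f"total mPD timepoints: {report['n_mpd_timepoints']}")
    for key in ("pfs_1y_mcr", "pfs_1y_non_mcr"):
        if key in report:
            lines.append(f"{key}: {100 * report[key]:.1f}%")
    if "floor_sensitivity_logrank_p" in report:
        lines.append(
            f"100 PPM floor re-clustering log-rank p: {report['floor_sensitivity_logrank_p']:.4f}"
        )
    path.write_text("\n".join(lines) + "\n")
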