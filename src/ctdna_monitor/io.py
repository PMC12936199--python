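"""Tabular interchange formats and the deposited-data adapter.

All inter-stage contracts are headered TSV files; days (treatment start =
0) are the universal time unit and PPM the universal level unit. Schemas
are documented in docs/formats.md and enforced on read with errors that
name the file and the offending columns.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "load_deposited",
]

SCHEMAS: dict[str, list[str]] = {
    "measurements": ["patient_id", "sample_day", "k", "N", "lambda"],
    "clinical": [
        "patient_id", "bor", "pfs_days", "pfs_event", "os_days", "os_event",
        "tmb", "msi", "treatment_class",
    ],
    "calls": ["patient_id", "sample_day", "ppm", "p_value", "detected", "lod_ppm"],
    "labels": [
        "patient_id", "mr_30", "mr_50", "mr_75", "mcr", "first_mpd_day",
        "n_mpd_timepoints", "lead_time_days",
    ],
    "clusters": ["patient_id", "cluster", "risk_label"],
    "spider": ["patient_id", "sample_day", "log10_ppm_plus1"],
    "survival_report": ["exposure", "endpoint", "hr", "ci_low", "ci_high", "p", "n"],
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a pipeline TSV, validating its schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing} for schema '{schema}' "
            f"(expected {required})"
        )
    if "detected" in df.columns:
        df["detected"] = df["detected"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a pipeline TSV (round-trips through read_table)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


# Column-name candidates for the deposited processed patient tables. The
# adapter maps whichever spelling it finds onto the internal schema; any
# unmapped extra columns are ignored.
_DEPOSITED_CALL_COLS = {
    "patient_id": ["patient_id", "Patient_ID", "patient", "subject_id"],
    "sample_day": ["sample_day", "day", "days_from_treatment_start", "timepoint_day", "time_days"],
    "ppm": ["ppm", "PPM", "ctdna_ppm", "ctDNA_PPM", "tumor_fraction_ppm"],
    "detected": ["detected", "ctdna_detected", "detection_status", "positive"],
}
_DEPOSITED_CLINICAL_COLS = {
    "patient_id": ["patient_id", "Patient_ID", "patient", "subject_id"],
    "bor": ["bor", "BOR", "best_overall_response", "best_response"],
    "pfs_days": ["pfs_days", "PFS_days", "pfs_time", "pfs"],
    "pfs_event": ["pfs_event", "PFS_event", "progression", "pfs_status"],
    "os_days": ["os_days", "OS_days", "os_time", "os"],
    "os_event": ["os_event", "OS_event", "death", "os_status"],
    "tmb": ["tmb", "TMB", "tmb_mut_mb"],
    "msi": ["msi", "MSI", "msi_status"],
}


def _map_columns(df: pd.DataFrame, mapping: dict[str, list[str]], path, required) -> pd.DataFrame:
    out = {}
    for target, candidates in mapping.items():
        found = next((c for c in candidates if c in df.columns), None)
        if found is not None:
            out[target] = df[found]
        elif target in required:
            raise ValueError(
                f"{path}: could not locate a column for '{target}' "
                f"(looked for {candidates}); found columns {list(df.columns)}"
            )
    return pd.DataFrame(out)


def load_deposited(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adapter from locally supplied deposited study tables to internal schemas.

    ``path`` is a directory containing the processed patient data obtained
    manually from the public archive (no network access is attempted). The
    adapter looks for a per-sample ctDNA table and a per-patient clinical
    table (csv/tsv/xlsx), maps recognized column spellings onto the
    internal ``calls`` / ``clinical`` schemas, fills assay-internal fields
    that processed releases do not carry (p_value, lod_ppm) with NaN, and
    ignores everything else.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"deposited data path not found: {path}")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".csv", ".tsv", ".txt", ".xlsx"}
    )
    if not files:
        raise ValueError(f"{path}: no tabular files found")

    def _read(p: Path) -> pd.DataFrame:
        if p.suffix.lower() == ".xlsx":
            return pd.read_excel(p)
        sep = "\t" if p.suffix.lower() in {".tsv", ".txt"} else ","
        df = pd.read_csv(p, sep=sep)
        if df.shape[1] == 1:  # wrong separator guess
            df = pd.read_csv(p, sep="," if sep == "\t" else "\t")
        return df

    calls = clinical = None
    for f in files:
        df = _read(f)
        if df.empty:
            raise ValueError(f"{f}: empty file")
        cols = set(df.columns)
        if calls is None and any(c in cols for c in _DEPOSITED_CALL_COLS["ppm"]):
            calls = _map_columns(
                df, _DEPOSITED_CALL_COLS, f, required={"patient_id", "sample_day", "ppm"}
            )
        elif clinical is None and any(c in cols for c in _DEPOSITED_CLINICAL_COLS["pfs_days"]):
            clinical = _map_columns(
                df, _DEPOSITED_CLINICAL_COLS, f, required={"patient_id", "pfs_days", "pfs_event"}
            )
    if calls is None or clinical is None:
        raise ValueError(
            f"{path}: could not identify both a per-sample ctDNA table and a "
            f"clinical table; expected columns like "
            f"{_DEPOSITED_CALL_COLS['ppm']} and {_DEPOSITED_CLINICAL_COLS['pfs_days']}"
        )
    if "detected" not in calls.columns:
        calls["detected"] = calls["ppm"] > 0
    calls["detected"] = calls["detected"].astype(bool)
    calls["p_value"] = np.nan
    calls["lod_ppm"] = np.nan
    calls = calls[SCHEMAS["calls"]]
    for col in ("tmb",):
        if col not in clinical.columns:
            clinical[col] = np.nan
    for col, default in (("msi", "MSS"), ("treatment_class", "unknown")):
        if col not in clinical.columns:
            clinical[col] = default
    if "os_days" not in clinical.columns:
        clinical["os_days"] = clinical["pfs_days"]
        clinical["os_event"] = 0
    clinical = clinical[[c for c in SCHEMAS["clinical"] if c in clinical.columns]]
    return calls, clinical
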