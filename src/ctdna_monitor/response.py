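"""Molecular response classification from longitudinal ctDNA calls.

Three label families are derived from a patient's ordered ctDNA timeline
(treatment start = day 0):

* **mR** (molecular response): >threshold reduction in ctDNA level from the
  baseline (first on-treatment) sample to the first follow-up sample in a
  configurable window, or sustained negativity across both. Thresholds of
  30%, 50% and 75% are computed side by side; 50% is the primary
  definition.
* **mCR** (molecular complete response): any undetected timepoint strictly
  after baseline — clearance must be demonstrated on treatment.
* **mPD** (molecular progressive disease): a detected sample whose level
  rose >= 30% above the lowest level at any strictly earlier timepoint
  (running minimum); re-detection after clearance counts.

The mR comparison is strict (">50%") while mPD is inclusive (">=30%"),
an asymmetry kept deliberately. Lead time is the number of days by which
the first mPD call precedes imaging-based progression (negative if it
follows it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .detect import CtdnaCall

__all__ = [
    "MrStatus",
    "PatientTimeline",
    "MolecularLabels",
    "select_baseline_and_followup",
    "call_mr",
    "call_mcr",
    "call_mpd",
    "compute_lead_time",
    "MolecularResponseLabeler",
]

DEFAULT_FOLLOWUP_WINDOW = (10.0, 45.0)
DEFAULT_MR_THRESHOLD = 0.5
DEFAULT_MPD_INCREASE = 0.3


class MrStatus(str, Enum):
    RESPONSE = "response"
    NO_RESPONSE = "no_response"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class PatientTimeline:
    """Ordered, day-stamped detection calls for one patient.

    ``samples`` is a list of ``(sample_day, CtdnaCall)`` with strictly
    increasing days; ``clinical_pd_day`` is the imaging-based progression
    day when one occurred. Days are offsets from treatment start.
    """

    patient_id: str
    samples: tuple[tuple[float, CtdnaCall], ...]
    clinical_pd_day: float | None = None
    treatment_start_day: float = 0.0

    def __post_init__(self) -> None:
        if len(self.samples) < 1:
            raise ValueError("timeline needs at least one sample")
        days = [d for d, _ in self.samples]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample days must be strictly increasing")

    @property
    def days(self) -> list[float]:
        return [d for d, _ in self.samples]

    @property
    def ppm(self) -> list[float]:
        return [c.ppm for _, c in self.samples]


@dataclass(frozen=True)
class MolecularLabels:
    """Derived exposure variables for one patient."""

    patient_id: str
    mr_30: MrStatus
    mr_50: MrStatus
    mr_75: MrStatus
    mcr: bool
    mpd_days: tuple[float, ...]
    lead_time_days: float | None

    @property
    def first_mpd_day(self) -> float | None:
        return self.mpd_days[0] if self.mpd_days else None


def select_baseline_and_followup(
    tl: PatientTimeline,
    followup_window: tuple[float, float] = DEFAULT_FOLLOWUP_WINDOW,
):
    """Pick the baseline sample and the first window-compatible follow-up.

    Baseline is the first sample at/after treatment start; follow-up is the
    earliest later sample whose gap from baseline lies inside
    ``followup_window`` (days). Returns ``(baseline, followup)`` as
    ``(day, CtdnaCall)`` tuples, or None if either is missing.
    """
    lo, hi = followup_window
    on_treatment = [(d, c) for d, c in tl.samples if d >= tl.treatment_start_day]
    if not on_treatment:
        return None
    base_day, base_call = on_treatment[0]
    for day, call in on_treatment[1:]:
        if lo <= day - base_day <= hi:
            return (base_day, base_call), (day, call)
    return None


def call_mr(
    baseline: CtdnaCall, followup: CtdnaCall, threshold: float = DEFAULT_MR_THRESHOLD
) -> MrStatus:
    """Molecular response between baseline and first follow-up.

    Response iff the reduction is strictly greater than ``threshold``
    (e.g. >50%), or both samples are undetected (sustained negativity).
    Conversion from negative baseline to positive follow-up is adverse:
    no_response.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if baseline.ppm > 0:
        reduction = 1.0 - followup.ppm / baseline.ppm
        return MrStatus.RESPONSE if reduction > threshold else MrStatus.NO_RESPONSE
    if not baseline.detected and not followup.detected:
        return MrStatus.RESPONSE
    return MrStatus.NO_RESPONSE


def call_mcr(tl: PatientTimeline, include_never_detected: bool = True) -> bool:
    """Molecular complete response: any post-baseline undetected timepoint.

    The baseline sample itself cannot qualify (clearance must be observed
    on treatment), so a single-sample timeline is never mCR. With
    ``include_never_detected=False`` the patient must additionally have at
    least one detected sample somewhere in the timeline.
    """
    post_baseline = tl.samples[1:]
    cleared = any(not call.detected for _, call in post_baseline)
    if cleared and not include_never_detected:
        return any(call.detected for _, call in tl.samples)
    return cleared


def call_mpd(
    tl: PatientTimeline,
    increase: float = DEFAULT_MPD_INCREASE,
    require_detected: bool = True,
) -> list[float]:
    """Sample days flagged molecular progressive disease.

    For every sample after the first, compare its level with the running
    minimum m over all strictly earlier samples: flag iff the sample is
    detected and either ``ppm >= (1 + increase) * m`` (m > 0) or the
    patient re-converted to positive after clearance (m == 0, ppm > 0).
    Undetected timepoints never trigger mPD while ``require_detected``.
    """
    if increase < 0:
        raise ValueError("increase must be >= 0")
    flagged: list[float] = []
    running_min = np.inf
    for i, (day, call) in enumerate(tl.samples):
        if i >= 1:
            ok = call.detected if require_detected else call.ppm > 0
            if ok and (
                (running_min > 0 and call.ppm >= (1.0 + increase) * running_min)
                or (running_min == 0 and call.ppm > 0)
            ):
                flagged.append(day)
        running_min = min(running_min, call.ppm)
    return flagged


def compute_lead_time(
    mpd_days: list[float] | tuple[float, ...], clinical_pd_day: float | None
) -> float | None:
    """Days between the first mPD call and imaging-based progression.

    ``clinical_pd_day - first_mpd_day``; None when either is missing;
    negative when molecular progression trailed imaging.
    """
    if not mpd_days or clinical_pd_day is None or np.isnan(clinical_pd_day):
        return None
    return clinical_pd_day - mpd_days[0]


class MolecularResponseLabeler(BaseEstimator, TransformerMixin):
    """Transformer from per-sample detection calls to per-patient labels.

    Parameters mirror the label definitions: ``mr_thresholds`` (computed
    side by side, default 30/50/75%), ``mpd_increase``, the baseline →
    follow-up ``followup_window`` in days, and the two definitional flags
    ``mcr_include_never_detected`` and ``mpd_require_detected``.
    """

    def __init__(
        self,
        mr_thresholds: tuple[float, ...] = (0.3, 0.5, 0.75),
        mpd_increase: float = DEFAULT_MPD_INCREASE,
        followup_window: tuple[float, float] = DEFAULT_FOLLOWUP_WINDOW,
        mcr_include_never_detected: bool = True,
        mpd_require_detected: bool = True,
    ):
        self.mr_thresholds = mr_thresholds
        self.mpd_increase = mpd_increase
        self.followup_window = followup_window
        self.mcr_include_never_detected = mcr_include_never_detected
        self.mpd_require_detected = mpd_require_detected

    def fit(self, X, y=None) -> "MolecularResponseLabeler":
        self.n_patients_seen_ = X["patient_id"].nunique()
        return self

    def label_timeline(self, tl: PatientTimeline) -> MolecularLabels:
        pair = select_baseline_and_followup(tl, self.followup_window)
        mr = {}
        for thr in self.mr_thresholds:
            if pair is None:
                mr[thr] = MrStatus.NOT_EVALUABLE
            else:
                (_, base), (_, fup) = pair
                mr[thr] = call_mr(base, fup, thr)
        mpd_days = tuple(
            call_mpd(tl, self.mpd_increase, self.mpd_require_detected)
        )
        return MolecularLabels(
            patient_id=tl.patient_id,
            mr_30=mr.get(0.3, MrStatus.NOT_EVALUABLE),
            mr_50=mr.get(0.5, MrStatus.NOT_EVALUABLE),
            mr_75=mr.get(0.75, MrStatus.NOT_EVALUABLE),
            mcr=call_mcr(tl, self.mcr_include_never_detected),
            mpd_days=mpd_days,
            lead_time_days=compute_lead_time(mpd_days, tl.clinical_pd_day),
        )

    def transform(self, X: pd.DataFrame, clinical: pd.DataFrame | None = None) -> pd.DataFrame:
        """Label every patient in a calls table.

        ``X`` is a calls DataFrame (patient_id, sample_day, ppm, p_value,
        detected, lod_ppm); ``clinical`` optionally supplies
        ``clinical_pd_day`` for lead-time computation. Returns one row per
        patient (labels table).
        """
        pd_days: dict[str, float] = {}
        if clinical is not None and "clinical_pd_day" in clinical.columns:
            pd_days = clinical.set_index("patient_id")["clinical_pd_day"].to_dict()
        rows = []
        for pid, grp in X.groupby("patient_id", sort=True):
            tl = timeline_from_calls(grp, pid, pd_days.get(pid))
            lab = self.label_timeline(tl)
            rows.append(
                {
                    "patient_id": pid,
                    "mr_30": lab.mr_30.value,
                    "mr_50": lab.mr_50.value,
                    "mr_75": lab.mr_75.value,
                    "mcr": lab.mcr,
                    "first_mpd_day": lab.first_mpd_day,
                    "n_mpd_timepoints": len(lab.mpd_days),
                    "lead_time_days": lab.lead_time_days,
                }
            )
        return pd.DataFrame(rows)


def timeline_from_calls(
    calls: pd.DataFrame, patient_id: str, clinical_pd_day: float | None = None
) -> PatientTimeline:
    """Build a :class:`PatientTimeline` from rows of a calls table."""
    grp = calls.sort_values("sample_day")
    samples = tuple(
        (
            float(r.sample_day),
            CtdnaCall(
                ppm=float(r.ppm),
                p_value=float(getattr(r, "p_value", 1.0)),
                detected=bool(r.detected),
                lod_ppm=float(getattr(r, "lod_ppm", np.nan)),
            ),
        )
        for r in grp.itertuples()
    )
    if clinical_pd_day is not None and np.isnan(clinical_pd_day):
        clinical_pd_day = None
    return PatientTimeline(
        patient_id=patient_id, samples=samples, clinical_pd_day=clinical_pd_day
    )
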