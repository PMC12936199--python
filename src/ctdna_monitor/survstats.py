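"""Survival and association statistics for molecular response labels.

Thin, explicitly-parameterized wrappers around lifelines (Kaplan–Meier,
Cox with Efron tie handling, log-rank) and scikit-survival (IPCW
cumulative/dynamic time-dependent AUC), plus an exact Freeman–Halton
(r x c Fisher) test implemented by exhaustive enumeration over tables with
fixed margins. Hazard ratios are reported with Wald confidence intervals,
the standard presentation for Cox model output.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalResult",
    "km_estimate",
    "cox_fit",
    "logrank_test",
    "fisher_exact_rxc",
    "time_dependent_auc",
]


@dataclass(frozen=True)
class SurvivalResult:
    """Per-covariate Cox regression summary (HR scale)."""

    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    flagged: bool = False  # convergence / separation warning raised

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high) and not self.flagged:
            raise ValueError("Wald CI must bracket the hazard ratio")


class KMEstimate:
    """Product-limit survival curve with step-function evaluation."""

    def __init__(self, times, events, label: str = "KM"):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events).astype(int)
        if times.size == 0:
            raise ValueError("empty survival input")
        if times.size != events.size:
            raise ValueError("times and events must have equal length")
        if np.any(times <= 0):
            raise ValueError("survival times must be positive")
        self._kmf = KaplanMeierFitter(label=label)
        self._kmf.fit(times, events)
        self.n = times.size

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be >= 0")
        return float(self._kmf.predict(t))

    @property
    def curve(self) -> pd.DataFrame:
        df = self._kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        return df


def km_estimate(times, events, label: str = "KM") -> KMEstimate:
    """Kaplan–Meier product-limit estimator; ``survival_at(t)`` evaluates it."""
    return KMEstimate(times, events, label)


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    ties: str = "efron",
) -> list[SurvivalResult]:
    """Cox proportional-hazards regression, one SurvivalResult per covariate.

    Efron partial-likelihood tie handling (the lifelines and R `survival`
    default); Wald CIs and p-values; HR = exp(coefficient). Monotone
    likelihood / separation surfaces as ``flagged=True`` rather than a
    silent divergence.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if events.sum() < 1:
        raise ValueError("Cox regression needs at least one event")
    nunique = covariates.nunique()
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        raise ValueError(f"constant covariates: {constant}")
    df = covariates.copy().astype(float)
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="_time", event_col="_event")
        flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    summary = cph.summary
    out = []
    for cov in covariates.columns:
        row = summary.loc[cov]
        out.append(
            SurvivalResult(
                covariate=str(cov),
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                n=len(df),
                n_events=int(events.sum()),
                flagged=flagged,
            )
        )
    return out


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float


def logrank_test(times, events, group) -> LogrankResult:
    """Two-group log-rank test; p from chi-square with 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {levels.size}")
    a = group == levels[0]
    if np.array_equal(np.sort(times[a]), np.sort(times[~a])) and np.array_equal(
        np.sort(events[a]), np.sort(events[~a])
    ):
        # identical groups: statistic is exactly 0; avoid 0/0 in the variance
        return LogrankResult(0.0, 1.0)
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return LogrankResult(float(res.test_statistic), float(res.p_value))


def _log_table_prob(table: np.ndarray, row_sums, col_sums, n: int) -> float:
    """log multivariate hypergeometric probability of an r x c table."""
    num = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    den = lgamma(n + 1) + sum(lgamma(x + 1) for x in table.ravel())
    return num - den


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols, rows):
        if row_idx == r - 1:
            last = np.array(remaining_cols)
            if np.all(last >= 0):
                yield rows + [last]
            return
        target = row_sums[row_idx]

        def cells(col_idx, left, acc):
            if col_idx == c - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield acc + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from cells(col_idx + 1, left - v, acc + [v])

        for row in cells(0, target, []):
            rem = [rc - v for rc, v in zip(remaining_cols, row)]
            yield from rec(row_idx + 1, rem, rows + [np.array(row)])

    yield from rec(0, list(col_sums), [])


def fisher_exact_rxc(table, max_total: int = 200) -> float:
    """Freeman–Halton exact test for an r x c contingency table.

    Two-sided p: the sum of the probabilities of every table with the same
    margins whose multivariate hypergeometric probability does not exceed
    that of the observed table (with a small relative tolerance for
    floating-point ties). Exhaustive enumeration; practical for margin
    totals up to ~200 on small tables, which covers cohort-scale 2 x 3
    response-by-BOR tables comfortably.
    """
    obs = np.asarray(table, dtype=int)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    if not np.array_equal(obs, np.asarray(table)):
        raise ValueError("counts must be integers")
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("table must be at least 2 x 2")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = int(obs.sum())
    if n == 0 or np.any(row_sums == 0) or np.any(col_sums == 0):
        return 1.0  # a zero margin leaves a single attainable table
    if n > max_total:
        raise ValueError(f"margin total {n} exceeds enumeration limit {max_total}")
    log_p_obs = _log_table_prob(obs, row_sums, col_sums, n)
    cutoff = log_p_obs + 1e-7  # tolerate fp ties
    total = 0.0
    for t in _enumerate_tables(list(row_sums), list(col_sums)):
        lp = _log_table_prob(np.array(t), row_sums, col_sums, n)
        if lp <= cutoff:
            total += math.exp(lp)
    return min(total, 1.0)


def time_dependent_auc(marker, times, events, horizon: float) -> float:
    """IPCW cumulative-case / dynamic-control AUC at a fixed horizon.

    Cases are subjects with an event by ``horizon``; controls are those
    still event-free; censoring is handled by inverse-probability-of-
    censoring weights from a Kaplan–Meier estimate of the censoring
    distribution (scikit-survival's estimator). Raises when no cases or no
    controls exist at the horizon.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if horizon <= 0 or horizon >= times.max():
        raise ValueError("horizon must lie within observed follow-up")
    n_cases = int(np.sum(events & (times <= horizon)))
    n_controls = int(np.sum(times > horizon))
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"AUC undefined at horizon {horizon}: {n_cases} cases, {n_controls} controls"
        )
    y = Surv.from_arrays(event=events, time=times)
    auc, _ = cumulative_dynamic_auc(y, y, marker, [horizon])
    return float(auc[0])
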