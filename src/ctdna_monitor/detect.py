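"""Poisson-model ctDNA detection and quantification.

A tumor-informed panel tracks ~1,800 patient-specific somatic variants in
cell-free DNA. For one plasma sample the panel yields an aggregate count
``k`` of tumor-supporting molecules over ``N`` informative molecules, with
an expected background (sequencing-error) molecule count
``lambda = sum_i depth_i * error_i``. Detection is a one-tailed exact
Poisson test of ``k`` against that background, and the tumor fraction is
reported in parts per million (PPM = tumor fraction x 1e6) under a
heterozygous-diploid convention (a tumor-derived molecule carries the
tracked allele with probability tf/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PanelMeasurement",
    "CtdnaCall",
    "poisson_detection_test",
    "estimate_ppm",
    "estimate_lod",
    "apply_detection_floor",
    "PoissonDetector",
]

# smallest positive double; keeps p-values in (0, 1] even when lambda == 0
_TINY = np.nextafter(0.0, 1.0)

DEFAULT_ALPHA = 0.001
DEFAULT_POWER = 0.95


@dataclass(frozen=True)
class PanelMeasurement:
    """Aggregate panel readout for one plasma sample.

    Attributes
    ----------
    k : int
        Tumor-supporting molecule count summed over tracked sites.
    n_molecules : float
        Total informative molecules summed over tracked sites (N).
    background : float
        Expected background molecule count lambda = sum(depth_i * error_i).
    """

    k: int
    n_molecules: float
    background: float

    def __post_init__(self) -> None:
        if self.k < 0 or int(self.k) != self.k:
            raise ValueError(f"k must be a nonnegative integer, got {self.k}")
        if self.n_molecules <= 0:
            raise ValueError(f"N must be positive, got {self.n_molecules}")
        if self.background < 0:
            raise ValueError(f"lambda must be >= 0, got {self.background}")


@dataclass(frozen=True)
class CtdnaCall:
    """Detection call for one sample: PPM estimate, p-value, LOD."""

    ppm: float
    p_value: float
    detected: bool
    lod_ppm: float

    def with_floor(self) -> "CtdnaCall":
        return replace(self, detected=False, ppm=0.0)


def poisson_detection_test(
    k, background, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """One-tailed exact Poisson test of observed counts against background.

    p = P(X >= k) for X ~ Poisson(lambda), so k = 0 gives p = 1. A sample
    is called detected (ctDNA-positive) when p <= alpha. Accepts scalars or
    arrays; the exact upper tail is used throughout — in the ultrasensitive
    regime k is of order 1-10 and a normal approximation would be badly
    anticonservative.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    k_arr = np.asarray(k)
    lam = np.asarray(background, dtype=float)
    if np.any(lam < 0):
        raise ValueError("background (lambda) must be >= 0")
    if np.any(k_arr < 0):
        raise ValueError("counts must be >= 0")
    # P(X >= k) = sf(k - 1); clamp so the p-value stays in (0, 1]
    p = np.maximum(stats.poisson.sf(k_arr - 1, lam), _TINY)
    detected = p <= alpha
    if np.isscalar(k) or k_arr.ndim == 0:
        return float(p), bool(detected)
    return p, detected


def estimate_ppm(
    k, n_molecules, background, background_correction: bool = True
) -> np.ndarray | float:
    """Point estimate of tumor fraction in PPM.

    Under the heterozygous-diploid convention the expected tumor-supporting
    count is N * tf / 2 + lambda, so the moment estimator is
    ``ppm = 1e6 * max(0, 2 * (k - lambda) / N)``. Background subtraction can
    be disabled, in which case ``ppm = 1e6 * 2k / N``.
    """
    k_arr = np.asarray(k, dtype=float)
    n = np.asarray(n_molecules, dtype=float)
    lam = np.asarray(background, dtype=float)
    if np.any(n <= 0):
        raise ValueError("N must be positive")
    signal = k_arr - lam if background_correction else k_arr
    ppm = 1e6 * np.maximum(0.0, 2.0 * signal / n)
    if np.isscalar(k) and np.isscalar(n_molecules):
        return float(ppm)
    return ppm


def _critical_count(background: float, alpha: float) -> int:
    """Smallest k with P(X >= k | lambda) <= alpha."""
    # isf gives approximately the right quantile; walk to the exact minimum
    k = int(stats.poisson.isf(alpha, background)) if background > 0 else 1
    k = max(k, 1)
    while stats.poisson.sf(k - 1, background) > alpha:
        k += 1
    while k > 1 and stats.poisson.sf(k - 2, background) <= alpha:
        k -= 1
    return k


def estimate_lod(
    n_molecules: float,
    background: float,
    alpha: float = DEFAULT_ALPHA,
    power: float = DEFAULT_POWER,
    rel_tol: float = 1e-6,
) -> float:
    """Per-sample limit of detection in PPM.

    The LOD is the smallest tumor fraction detected with probability
    >= ``power`` at significance ``alpha``: find the critical count
    k_crit = min{k : P(X >= k | lambda) <= alpha}, then the smallest total
    Poisson mean mu* >= lambda with P(X >= k_crit | mu*) >= power (by
    bisection), and convert the signal mean back to a tumor fraction:
    ``lod_ppm = 1e6 * 2 * (mu* - lambda) / N``.
    """
    if n_molecules <= 0:
        raise ValueError("N must be positive")
    if background < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0,1)")
    k_crit = _critical_count(background, alpha)

    def tail_power(mu: float) -> float:
        return stats.poisson.sf(k_crit - 1, mu)

    lo = background
    hi = max(2.0 * background, float(k_crit), 1.0)
    while tail_power(hi) < power:
        hi *= 2.0
    # tail_power is strictly increasing in mu
    while hi - lo > rel_tol * max(hi, 1.0):
        mid = 0.5 * (lo + hi)
        if tail_power(mid) >= power:
            hi = mid
        else:
            lo = mid
    mu_star = hi
    return 1e6 * 2.0 * (mu_star - background) / n_molecules


def apply_detection_floor(calls, floor_ppm: float = 100.0):
    """Reclassify calls below a PPM floor as undetected (sensitivity analysis).

    Any call with ppm strictly below ``floor_ppm`` becomes undetected with
    ppm 0; other calls are unchanged. The input is not mutated. Accepts a
    list of :class:`CtdnaCall` or a calls DataFrame (columns ``ppm``,
    ``detected``).
    """
    if floor_ppm < 0:
        raise ValueError("floor_ppm must be >= 0")
    if isinstance(calls, pd.DataFrame):
        out = calls.copy()
        mask = out["ppm"] < floor_ppm
        out.loc[mask, "detected"] = False
        out.loc[mask, "ppm"] = 0.0
        return out
    return [c.with_floor() if c.ppm < floor_ppm else c for c in calls]


class PoissonDetector(BaseEstimator, TransformerMixin):
    """Transformer turning panel measurements into ctDNA detection calls.

    Parameters
    ----------
    alpha : float, default 0.001
        One-tailed Poisson significance threshold (detected iff p <= alpha).
    power : float, default 0.95
        Power level defining the per-sample limit of detection.
    floor_ppm : float or None, default None
        Optional PPM floor; calls below it are reclassified undetected
        (the 100 PPM sensitivity analysis).
    background_correction : bool, default True
        Subtract the expected background molecule count when estimating PPM.

    The transformer is stateless (``fit`` records nothing but column
    bookkeeping); it exists so detection composes with sklearn pipelines.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        power: float = DEFAULT_POWER,
        floor_ppm: float | None = None,
        background_correction: bool = True,
    ):
        self.alpha = alpha
        self.power = power
        self.floor_ppm = floor_ppm
        self.background_correction = background_correction

    def fit(self, X: pd.DataFrame, y=None) -> "PoissonDetector":
        self._validate(X)
        self.n_samples_seen_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Map a measurements table (k, N, lambda per sample) to calls.

        Returns a DataFrame with columns ``ppm``, ``p_value``, ``detected``,
        ``lod_ppm`` appended to any identifier columns present
        (``patient_id``, ``sample_day``).
        """
        self._validate(X)
        p, detected = poisson_detection_test(
            X["k"].to_numpy(), X["lambda"].to_numpy(), self.alpha
        )
        ppm = estimate_ppm(
            X["k"].to_numpy(),
            X["N"].to_numpy(),
            X["lambda"].to_numpy(),
            self.background_correction,
        )
        ppm = np.where(detected, ppm, 0.0)  # negativity is a state: report 0
        # samples sharing a panel share (N, lambda); compute each LOD once
        lod_cache: dict[tuple[float, float], float] = {}
        lod = np.empty(len(X))
        for i, (n, lam) in enumerate(zip(X["N"].to_numpy(), X["lambda"].to_numpy())):
            key = (n, lam)
            if key not in lod_cache:
                lod_cache[key] = estimate_lod(n, lam, self.alpha, self.power)
            lod[i] = lod_cache[key]
        cols = [c for c in ("patient_id", "sample_day") if c in X.columns]
        out = X[cols].copy() if cols else pd.DataFrame(index=X.index)
        out["ppm"] = ppm
        out["p_value"] = p
        out["detected"] = detected
        out["lod_ppm"] = lod
        if self.floor_ppm is not None:
            out = apply_detection_floor(out, self.floor_ppm)
        return out

    def call_one(self, m: PanelMeasurement) -> CtdnaCall:
        """Detection call for a single :class:`PanelMeasurement`."""
        p, det = poisson_detection_test(m.k, m.background, self.alpha)
        ppm = estimate_ppm(
            m.k, m.n_molecules, m.background, self.background_correction
        )
        call = CtdnaCall(
            ppm=float(ppm) if det else 0.0,
            p_value=p,
            detected=det,
            lod_ppm=estimate_lod(m.n_molecules, m.background, self.alpha, self.power),
        )
        if self.floor_ppm is not None and call.ppm < self.floor_ppm:
            call = call.with_floor()
        return call

    @staticmethod
    def _validate(X: pd.DataFrame) -> None:
        missing = {"k", "N", "lambda"} - set(X.columns)
        if missing:
            raise ValueError(f"measurements table missing columns: {sorted(missing)}")
        if (X["N"] <= 0).any():
            raise ValueError("N must be positive for every sample")
        if (X["lambda"] < 0).any():
            raise ValueError("lambda must be >= 0 for every sample")
        if (X["k"] < 0).any():
            raise ValueError("k must be >= 0 for every sample")
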