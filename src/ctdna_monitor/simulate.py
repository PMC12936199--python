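"""Synthetic cohorts for ultrasensitive ctDNA monitoring.

Generates tumor-informed panel data (per-site background error rates and
molecule depths), per-timepoint aggregate molecule counts, and linked
clinical records, with the statistical structure the downstream analysis
assumes:

* tumor fractions spanning roughly 2 to 240,000 PPM across the cohort,
  with about a third of positive detections in the sub-100-PPM range;
* four longitudinal trajectory archetypes — rapid clearance, partial
  decline to a plateau, persistence, and regrowth after an initial dip;
* progression/death hazards that depend only on the (hidden) archetype,
  so hazard-ratio recovery targets are well defined;
* best-overall-response labels drawn with archetype-dependent
  probabilities calibrated to a cohort that is ~37% PR / ~53% SD / ~11% PD.

Counts are generated per site as Poisson with mean
``depth_i * (tf/2 + error_i)`` (heterozygous-diploid convention), the exact
generative counterpart of the Poisson detection null, so parameter recovery
is exact in expectation. Simulation starts at consensus molecule counts;
no read-level or sequence-level simulation is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AssayConfig",
    "TrajectoryArchetype",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_ARCHETYPE_MIX",
    "simulate_panel",
    "simulate_sample_counts",
    "simulate_cohort",
]


@dataclass(frozen=True)
class AssayConfig:
    """Tumor-informed panel assay parameters.

    error_rate_bounds are the bounds of a log-uniform distribution of
    per-site per-molecule background error probabilities; depth_mean /
    depth_shape parametrize a Gamma distribution of mean informative
    molecules per site (overdispersed relative to a fixed depth).
    """

    n_sites: int = 1800
    error_rate_bounds: tuple[float, float] = (1e-7, 1e-5)
    depth_mean: float = 2000.0
    depth_shape: float = 10.0
    het_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        lo, hi = self.error_rate_bounds
        if not (0 < lo <= hi < 1):
            raise ValueError(f"error rate bounds must satisfy 0 < lo <= hi < 1, got {self.error_rate_bounds}")
        if self.depth_mean <= 0 or self.depth_shape <= 0:
            raise ValueError("depth distribution parameters must be positive")
        if not 0 < self.het_fraction <= 1:
            raise ValueError("het_fraction must be in (0,1]")


@dataclass(frozen=True)
class TrajectoryArchetype:
    """Parametric longitudinal tumor-fraction trajectory.

    ``baseline_log10_ppm`` gives the (mean, sd) of log10 baseline PPM;
    rates are per-day multiplicative; ``hazard_multiplier`` scales the
    progression/death hazard relative to the cohort base hazard;
    ``noise_sd_log`` is the sd of per-sample lognormal biological noise
    (natural-log scale).
    """

    name: str
    baseline_log10_ppm: tuple[float, float]
    decay_rate: float = 0.0
    growth_rate: float = 0.0
    plateau_fraction: float = 0.0
    clearance_day: tuple[float, float] | None = None
    hazard_multiplier: float = 1.0
    noise_sd_log: float = 0.25
    bor_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # PR, SD, PD

    def __post_init__(self) -> None:
        if self.hazard_multiplier <= 0:
            raise ValueError("hazard_multiplier must be > 0")
        if abs(sum(self.bor_probs) - 1.0) > 1e-9:
            raise ValueError("bor_probs must sum to 1")

    def true_tf(self, day: float, baseline_ppm: float, clearance_day: float | None) -> float:
        """Noise-free true tumor fraction at a given day post treatment start."""
        if clearance_day is not None and day >= clearance_day:
            return 0.0
        base = baseline_ppm * 1e-6
        if self.name == "regrowth":
            # decline toward a nadir, then exponential regrowth
            level = base * max(
                math.exp(-self.decay_rate * day),
                self.plateau_fraction * math.exp(self.growth_rate * day),
            )
        else:
            frac = self.plateau_fraction + (1 - self.plateau_fraction) * math.exp(
                -self.decay_rate * day
            )
            level = base * frac * math.exp(self.growth_rate * day)
        return min(level, 0.5)


# Defaults emulate the observed regimes: clearers drop fast and go negative,
# partial responders plateau around 20% of baseline, persisters wobble at a
# high level, regrowers dip then rebound past radiographic progression.
DEFAULT_ARCHETYPES: dict[str, TrajectoryArchetype] = {
    "clearance": TrajectoryArchetype(
        name="clearance",
        baseline_log10_ppm=(2.4, 0.9),
        decay_rate=0.10,
        clearance_day=(40.0, 80.0),
        hazard_multiplier=0.15,
        noise_sd_log=0.20,
        bor_probs=(0.75, 0.25, 0.00),
    ),
    "partial_response": TrajectoryArchetype(
        name="partial_response",
        baseline_log10_ppm=(2.75, 0.9),
        decay_rate=0.08,
        plateau_fraction=0.15,
        hazard_multiplier=0.5,
        noise_sd_log=0.25,
        bor_probs=(0.30, 0.65, 0.05),
    ),
    "persistence": TrajectoryArchetype(
        name="persistence",
        baseline_log10_ppm=(3.5, 0.8),
        growth_rate=0.006,
        hazard_multiplier=1.5,
        noise_sd_log=0.35,
        bor_probs=(0.05, 0.65, 0.30),
    ),
    "regrowth": TrajectoryArchetype(
        name="regrowth",
        baseline_log10_ppm=(3.1, 0.8),
        decay_rate=0.06,
        plateau_fraction=0.05,
        growth_rate=0.02,
        hazard_multiplier=2.5,
        noise_sd_log=0.30,
        bor_probs=(0.05, 0.60, 0.35),
    ),
}

DEFAULT_ARCHETYPE_MIX: dict[str, float] = {
    "clearance": 0.35,
    "partial_response": 0.30,
    "persistence": 0.20,
    "regrowth": 0.15,
}

# cohort base progression hazard: median PFS 180 days at multiplier 1
BASE_PFS_HAZARD = math.log(2) / 180.0
BASE_OS_EXTRA_HAZARD = math.log(2) / 240.0
ADMIN_CENSOR_RANGE = (365.0, 1095.0)


def simulate_panel(config: AssayConfig, seed: int) -> pd.DataFrame:
    """Draw a tumor-informed panel: per-site error rates and mean depths.

    Returns a DataFrame with one row per tracked variant: placeholder
    genomic coordinates plus ``error_rate`` (log-uniform within the
    configured bounds) and ``depth`` (Gamma, mean ``depth_mean``).
    """
    rng = np.random.default_rng(seed)
    lo, hi = config.error_rate_bounds
    err = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_sites))
    depth = rng.gamma(config.depth_shape, config.depth_mean / config.depth_shape, config.n_sites)
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, config.n_sites)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return pd.DataFrame(
        {
            "chrom": rng.integers(1, 23, config.n_sites).astype(str),
            "pos": rng.integers(1, 249_000_000, config.n_sites),
            "ref": ref,
            "alt": alt,
            "error_rate": err,
            "depth": depth,
        }
    )


def simulate_sample_counts(
    true_tf: float, sites: pd.DataFrame, seed: int | np.random.Generator
) -> dict:
    """Generate one sample's aggregate panel measurement.

    Per-site mutant molecule counts are Poisson with mean
    ``depth_i * (true_tf / 2 + error_i)``; the aggregate records
    ``k = sum(counts)``, ``N = sum(depths)`` and the background mass
    ``lambda = sum(depth_i * error_i)``.
    """
    if not 0 <= true_tf <= 1:
        raise ValueError(f"true tumor fraction must be in [0,1], got {true_tf}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    depth = sites["depth"].to_numpy()
    err = sites["error_rate"].to_numpy()
    mean = depth * (true_tf / 2.0 + err)
    counts = rng.poisson(mean)
    return {
        "k": int(counts.sum()),
        "N": float(depth.sum()),
        "lambda": float((depth * err).sum()),
    }


def _sample_days(rng: np.random.Generator, n_samples: int) -> np.ndarray:
    """On-treatment sampling schedule: ~day 4, ~day 27, then every ~42 days."""
    day0 = max(0.0, 4.0 + rng.uniform(-3, 3))
    days = [day0, day0 + 23.0 + rng.uniform(-5, 5)]
    while len(days) < n_samples:
        days.append(days[-1] + 42.0 + rng.uniform(-5, 5))
    return np.round(np.asarray(days[:n_samples])).astype(int)


def simulate_cohort(
    n_patients: int,
    archetype_mix: dict[str, float] | None = None,
    assay: AssayConfig | None = None,
    seed: int = 0,
    archetypes: dict[str, TrajectoryArchetype] | None = None,
    shared_panel: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a monitored cohort.

    Returns ``(measurements, clinical)``: per-timepoint aggregate counts
    (patient_id, sample_day, k, N, lambda, true_tf) and per-patient
    clinical records (bor, pfs_days/pfs_event, os_days/os_event, tmb, msi,
    treatment_class, true_archetype). ``true_archetype`` and ``true_tf``
    are hidden truth columns for recovery tests only — the analysis code
    never reads them.

    With ``shared_panel`` each patient reuses one simulated panel design
    (cheap, statistically equivalent at the aggregate level); set it False
    to redraw ~1,800 sites per patient.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    mix = dict(DEFAULT_ARCHETYPE_MIX if archetype_mix is None else archetype_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("archetype mix proportions must sum to 1")
    assay = assay or AssayConfig()
    arch_defs = archetypes or DEFAULT_ARCHETYPES
    unknown = set(mix) - set(arch_defs)
    if unknown:
        raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    panel = simulate_panel(assay, seed=rng.integers(2**31))

    names = list(mix)
    probs = np.array([mix[n] for n in names])
    meas_rows, clin_rows = [], []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        arch = arch_defs[names[rng.choice(len(names), p=probs)]]
        if not shared_panel:
            panel = simulate_panel(assay, seed=rng.integers(2**31))
        baseline_ppm = 10 ** rng.normal(*arch.baseline_log10_ppm)
        clearance_day = (
            rng.uniform(*arch.clearance_day) if arch.clearance_day is not None else None
        )
        days = _sample_days(rng, int(rng.integers(4, 10)))
        for day in days:
            tf = arch.true_tf(float(day), baseline_ppm, clearance_day)
            if tf > 0:
                tf = min(tf * rng.lognormal(0.0, arch.noise_sd_log), 0.5)
            m = simulate_sample_counts(tf, panel, rng)
            meas_rows.append(
                {"patient_id": pid, "sample_day": int(day), **m, "true_tf": tf}
            )

        mult = arch.hazard_multiplier
        pfs_t = rng.exponential(1.0 / (BASE_PFS_HAZARD * mult))
        os_t = pfs_t + rng.exponential(1.0 / (BASE_OS_EXTRA_HAZARD * math.sqrt(mult)))
        censor = rng.uniform(*ADMIN_CENSOR_RANGE)
        bor = ("PR", "SD", "PD")[rng.choice(3, p=np.asarray(arch.bor_probs))]
        clin_rows.append(
            {
                "patient_id": pid,
                "bor": bor,
                "pfs_days": round(min(pfs_t, censor), 1),
                "pfs_event": int(pfs_t <= censor),
                "os_days": round(min(os_t, censor), 1),
                "os_event": int(os_t <= censor),
                "tmb": round(float(10 ** rng.normal(0.63, 0.5)), 2),
                "msi": "MSI-H" if rng.random() < 0.10 else "MSS",
                "treatment_class": rng.choice(
                    ["IO", "IO+chemo", "IO+targeted", "IO+targeted+chemo"],
                    p=[0.31, 0.26, 0.23, 0.20],
                ),
                "true_archetype": arch.name,
                "clinical_pd_day": round(pfs_t, 1) if pfs_t <= censor else np.nan,
            }
        )
    measurements = pd.DataFrame(meas_rows)
    clinical = pd.DataFrame(clin_rows)
    return measurements, clinical
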