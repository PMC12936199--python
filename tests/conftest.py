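import numpy as np
import pandas as pd
import pytest

from ctdna_monitor.detect import CtdnaCall
from ctdna_monitor.response import PatientTimeline


def make_call(ppm: float, detected: bool | None = None) -> CtdnaCall:
    """Detection call with the given level; detected defaults to ppm > 0."""
    if detected is None:
        detected = ppm > 0
    return CtdnaCall(ppm=ppm, p_value=0.0001 if detected else 1.0,
                     detected=detected, lod_ppm=2.0)


def make_timeline(ppm_series, days=None, clinical_pd_day=None, patient_id="T01"):
    if days is None:
        days = [4 + 23 * i for i in range(len(ppm_series))]
    samples = tuple((float(d), make_call(float(p))) for d, p in zip(days, ppm_series))
    return PatientTimeline(patient_id=patient_id, samples=samples,
                          clinical_pd_day=clinical_pd_day)


def random_timeline(rng: np.random.Generator, patient_id="R01") -> PatientTimeline:
    """Random timeline mixing detected levels and cleared (zero) timepoints."""
    n = int(rng.integers(2, 9))
    days = np.cumsum(rng.integers(5, 50, size=n)).astype(float)
    ppm = np.where(rng.random(n) < 0.3, 0.0, 10 ** rng.uniform(0.3, 5.0, n))
    pd_day = float(days[-1] + rng.integers(1, 200)) if rng.random() < 0.5 else None
    samples = tuple((d, make_call(float(p))) for d, p in zip(days, ppm))
    return PatientTimeline(patient_id=patient_id, samples=samples,
                          clinical_pd_day=pd_day)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-archetype cohort of 40 patients with detection calls."""
    from ctdna_monitor import PoissonDetector, simulate_cohort

    measurements, clinical = simulate_cohort(40, seed=101)
    calls = PoissonDetector().fit(measurements).transform(measurements)
    return measurements, clinical, calls
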