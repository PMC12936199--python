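"""Molecular response labels: mR, mCR, mPD, lead time."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_call, make_timeline, random_timeline
from ctdna_monitor.response import (
    MolecularResponseLabeler,
    MrStatus,
    call_mcr,
    call_mpd,
    call_mr,
    compute_lead_time,
    select_baseline_and_followup,
)


def running_min_mpd_oracle(timeline, increase=0.3):
    """Independent re-implementation scanning prefixes of the series."""
    flagged = []
    for i, (day, call) in enumerate(timeline.samples):
        if i == 0 or not call.detected:
            continue
        prev = [c.ppm for _, c in timeline.samples[:i]]
        m = min(prev)
        if (m > 0 and call.ppm >= (1 + increase) * m) or (m == 0 and call.ppm > 0):
            flagged.append(day)
    return flagged


class TestBaselineFollowupSelection:
    def test_standard_schedule(self):
        tl = make_timeline([100, 40, 10], days=[4, 27, 90])
        (bd, _), (fd, _) = select_baseline_and_followup(tl)
        assert (bd, fd) == (4, 27)

    def test_missing_followup(self):
        assert select_baseline_and_followup(make_timeline([100], days=[4])) is None
        assert select_baseline_and_followup(make_timeline([100, 10], days=[4, 120])) is None

    def test_earliest_window_compatible_sample_wins(self):
        tl = make_timeline([100, 50, 20], days=[0, 12, 40])
        (_, _), (fd, _) = select_baseline_and_followup(tl)
        assert fd == 12


class TestCallMr:
    @pytest.mark.parametrize(
        "base, fup, thr, expected",
        [
            (1000, 400, 0.5, MrStatus.RESPONSE),      # 60% reduction
            (1000, 500, 0.5, MrStatus.NO_RESPONSE),   # exactly 50%: strict >
            (0, 0, 0.5, MrStatus.RESPONSE),           # sustained negativity
            (0, 50, 0.5, MrStatus.NO_RESPONSE),       # conversion is adverse
            (1000, 0, 0.75, MrStatus.RESPONSE),       # clearance beats any threshold
        ],
    )
    def test_rule(self, base, fup, thr, expected):
        assert call_mr(make_call(base), make_call(fup), thr) is expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_mr(make_call(10), make_call(1), threshold=1.0)

    @given(
        base=st.floats(1.0, 1e6),
        ratio=st.floats(0.0, 1.5),
        t1=st.floats(0.05, 0.95),
        t2=st.floats(0.05, 0.95),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_threshold(self, base, ratio, t1, t2):
        """Response at a stringent threshold implies it at a permissive one."""
        lo, hi = sorted((t1, t2))
        b, f = make_call(base), make_call(base * ratio)
        if call_mr(b, f, hi) is MrStatus.RESPONSE:
            assert call_mr(b, f, lo) is MrStatus.RESPONSE


class TestCallMcr:
    @pytest.mark.parametrize(
        "series, expected",
        [
            ([500, 80, 0, 0], True),    # clearance present
            ([500, 800, 300], False),   # never cleared
            ([0], False),               # no on-treatment evidence
            ([0, 0], True),             # sustained negativity post-baseline
            ([0, 50, 100], False),      # baseline negativity alone never counts
        ],
    )
    def test_rule(self, series, expected):
        assert call_mcr(make_timeline(series)) is expected

    def test_never_detected_flag(self):
        tl = make_timeline([0, 0, 0])
        assert call_mcr(tl, include_never_detected=True) is True
        assert call_mcr(tl, include_never_detected=False) is False


class TestCallMpd:
    @pytest.mark.parametrize(
        "series, expected_idx",
        [
            ([100, 40, 60], [2]),       # 60 >= 1.3 * 40
            ([100, 40, 52.1], [2]),     # just past the +30% boundary
            ([100, 40, 50], []),        # 50 < 52
            ([100, 0, 5], [2]),         # re-detection after clearance
            ([10, 100, 200], [1, 2]),   # rises over the first sample
            ([100], []),
        ],
    )
    def test_rule(self, series, expected_idx):
        tl = make_timeline(series)
        assert call_mpd(tl) == [tl.days[i] for i in expected_idx]

    def test_first_sample_never_flagged(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tl = random_timeline(rng)
            assert tl.days[0] not in call_mpd(tl)

    def test_undetected_sample_cannot_trigger(self):
        tl = make_timeline([100, 10, 0])
        assert call_mpd(tl) == []

    def test_matches_running_minimum_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            tl = random_timeline(rng)
            assert call_mpd(tl) == running_min_mpd_oracle(tl)

    def test_invalid_increase(self):
        with pytest.raises(ValueError):
            call_mpd(make_timeline([1, 2]), increase=-0.1)


class TestLeadTime:
    def test_sign_convention_and_absence(self):
        assert compute_lead_time([22.0], 182.0) == 160.0
        assert compute_lead_time([200.0], 180.0) == -20.0
        assert compute_lead_time([], 180.0) is None
        assert compute_lead_time([22.0], None) is None


class TestLabeler:
    def test_scaling_invariance_of_all_labels(self):
        """Multiplying every PPM by a positive constant changes no label."""
        labeler = MolecularResponseLabeler()
        rng = np.random.default_rng(31)
        for _ in range(200):
            tl = random_timeline(rng)
            scaled = make_timeline(
                [c.ppm * 137.5 for _, c in tl.samples],
                days=tl.days,
                clinical_pd_day=tl.clinical_pd_day,
            )
            a, b = labeler.label_timeline(tl), labeler.label_timeline(scaled)
            assert (a.mr_30, a.mr_50, a.mr_75, a.mcr) == (b.mr_30, b.mr_50, b.mr_75, b.mcr)
            assert a.mpd_days == b.mpd_days and a.lead_time_days == b.lead_time_days

    def test_transform_schema_and_evaluability(self, small_cohort):
        _, clinical, calls = small_cohort
        labels = MolecularResponseLabeler().fit(calls).transform(calls, clinical)
        assert len(labels) == calls["patient_id"].nunique()
        assert set(labels["mr_50"]) <= {"response", "no_response", "not_evaluable"}
        # a patient with a lone sample is not evaluable for mR and not mCR
        lone = calls[calls["patient_id"] == calls["patient_id"].iloc[0]].iloc[:1]
        lab = MolecularResponseLabeler().transform(lone)
        assert lab["mr_50"].iloc[0] == "not_evaluable" and not lab["mcr"].iloc[0]

    def test_archetype_calibration(self, small_cohort):
        """Clearance patients should be mCR, persistence patients mPD."""
        _, clinical, calls = small_cohort
        labels = MolecularResponseLabeler().fit(calls).transform(calls, clinical)
        m = labels.merge(clinical, on="patient_id")
        clear = m[m["true_archetype"] == "clearance"]
        persist = m[m["true_archetype"] == "persistence"]
        assert clear["mcr"].mean() >= 0.95
        assert (persist["n_mpd_timepoints"] > 0).mean() >= 0.8
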