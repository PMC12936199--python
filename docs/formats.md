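# File formats

All pipeline tables are tab-separated with a header row. Days are integer
offsets from treatment start (day 0); ctDNA levels are in PPM
(tumor fraction × 10⁶).

## measurements.tsv — per-sample panel aggregates
| column | type | meaning |
|---|---|---|
| patient_id | str | patient identifier |
| sample_day | int | days from treatment start |
| k | int | tumor-supporting molecule count (panel aggregate) |
| N | float | total informative molecules |
| lambda | float | expected background molecule count Σ depthᵢ·errorᵢ |
| true_tf | float | (simulated cohorts only) hidden true tumor fraction |

## clinical.tsv — per-patient outcomes
| column | type | meaning |
|---|---|---|
| patient_id | str | |
| bor | str | best overall response: PR / SD / PD |
| pfs_days, pfs_event | float, 0/1 | progression-free survival, event flag |
| os_days, os_event | float, 0/1 | overall survival, event flag |
| tmb | float | tumor mutational burden, mutations/Mb |
| msi | str | MSI-H / MSS |
| treatment_class | str | IO / IO+chemo / IO+targeted / IO+targeted+chemo |
| true_archetype | str | (simulated only) hidden generating archetype |
| clinical_pd_day | float | imaging-based progression day, empty if none |

## calls.tsv — detection calls
patient_id, sample_day, ppm (0 when undetected), p_value (one-tailed
Poisson), detected (True/False), lod_ppm (per-sample LOD at 95% power).

## labels.tsv — per-patient molecular response labels
patient_id, mr_30, mr_50, mr_75 (response / no_response / not_evaluable),
mcr (True/False), first_mpd_day, n_mpd_timepoints, lead_time_days.

## clusters.tsv
patient_id, cluster (0/1), risk_label (high/low).

## spider_data.tsv — plot-ready trajectories
patient_id, sample_day, log10_ppm_plus1.

## survival_report.tsv
exposure, endpoint (pfs/os), hr, ci_low, ci_high, p, n — one row per
fitted association.
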