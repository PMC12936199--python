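# ctdna-monitor

Ultrasensitive, tumor-informed circulating tumor DNA (ctDNA) monitoring for
patients on immune checkpoint inhibitors — from raw panel molecule counts to
molecular response labels, trajectory clusters and survival statistics.

A tumor-informed assay tracks ~1,800 patient-specific somatic variants in
plasma cell-free DNA. Aggregating over the panel gives, per sample, a
tumor-supporting molecule count *k* out of *N* informative molecules with an
expected background (error) count λ = Σᵢ depthᵢ·errorᵢ. This package
implements the analysis layer on top of those counts:

* **Detection & quantification** — a one-tailed exact Poisson test of
  *k* against λ (positive iff P(X ≥ k | λ) ≤ 0.001), tumor fraction in parts
  per million, PPM = 10⁶ · max(0, 2(k − λ)/N) under the heterozygous-diploid
  convention, and a per-sample limit of detection (smallest tumor fraction
  detected with 95% power).
* **Molecular response** — mR: >50% (also 30%/75%) ctDNA reduction from the
  baseline to the first on-treatment follow-up, or sustained negativity;
  mCR: any post-baseline ctDNA-negative timepoint; mPD: a detected sample
  ≥30% above the lowest earlier level (running minimum), with the lead time
  of molecular over imaging-based progression.
* **Trajectory clustering** — dynamic time warping on log₁₀(PPM + 1) series,
  average-linkage clustering into high-/low-risk dynamic groups, and a
  100 PPM detection-floor sensitivity analysis.
* **Survival statistics** — Kaplan–Meier, Cox regression (Efron ties, Wald
  CIs), log-rank, an exact Freeman–Halton r×c association test, and IPCW
  time-dependent ROC AUC.
* **Synthetic cohorts** — a generator with clearance / partial-response /
  persistence / regrowth trajectory archetypes whose progression hazards
  depend on the archetype, so every stage is testable without patient data.

The core estimators follow scikit-learn conventions (`fit`/`transform`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn pipelines; module-level functions are thin wrappers.

## Worked example

```bash
ctdna run --n 39 --seed 7 --out demo_run
```

simulates a 39-patient cohort, runs detection, labelling, clustering and the
survival analyses, and prints (abridged):

```
median per-sample LOD: 10.12 PPM
fraction of detections < 100 PPM: 25.0%

mR (50%) by best overall response:
bor          PR  SD  PD
response     16  16   3
no_response   0   4   0
Freeman–Halton exact p = 0.1665

survival analyses:
 exposure endpoint        hr   ci_low   ci_high        p  n
    mr_50      pfs  0.471452 0.138444  1.605458 0.229078 39
      mcr      pfs  0.182553 0.072277  0.461086 0.000321 39
      mpd      pfs  7.263214 2.815431 18.737551 0.000041 39
high_risk_cluster pfs 5.083945 2.067836 12.499298 0.000396 39

median mPD lead time: 40.7 days
total mPD timepoints: 46
pfs_1y_mcr: 82.6%
100 PPM floor re-clustering log-rank p: 0.0012
```

Read: patients who clear ctDNA (mCR) progress at roughly a fifth the rate of
those who never clear (HR 0.18), molecular progression (mPD) multiplies the
progression hazard about sevenfold, and the high-risk trajectory cluster
carries a similar excess hazard — the directions the method is designed to
recover. At n = 39 the mR–PFS association is not individually significant
(HR 0.47, p = 0.23); at n = 200 it is (see the acceptance output).

The same stages are available individually (`ctdna simulate|detect|classify|
cluster|survival`), as a Python API (`ctdna_monitor.run_pipeline`,
`PoissonDetector`, `MolecularResponseLabeler`, `TrajectoryClusterer`, …),
and over externally supplied processed data via `ctdna load-zenodo <dir>`
(a local path to manually downloaded tables; nothing is fetched).

## Layout

```
src/ctdna_monitor/
  simulate.py    synthetic cohorts (archetypes, panel, counts, clinical)
  detect.py      Poisson detection, PPM, LOD, detection floor
  response.py    mR / mCR / mPD labels and lead time
  cluster.py     DTW distance, trajectory clustering, risk labels
  survstats.py   KM, Cox, log-rank, Freeman–Halton, time-dependent AUC
  io.py          TSV schemas and the deposited-data adapter
  pipeline.py    end-to-end orchestration
  cli.py         the `ctdna` command
docs/methods.md  model, assumptions, parameter choices, limitations
docs/formats.md  file schemas
```
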