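# Methods

## Detection model

A tumor-informed panel tracks ~1,800 patient-specific somatic variants. For
one plasma sample, site *i* contributes an informative molecule depth
*dᵢ* and a per-molecule background error probability *eᵢ*; the aggregate
observables are the tumor-supporting count k = Σᵢ kᵢ, the total molecule
count N = Σᵢ dᵢ, and the expected background mass λ = Σᵢ dᵢeᵢ.

Conditional on a true tumor fraction *tf*, each site's count is modelled
Poisson with mean dᵢ(tf/2 + eᵢ): tracked variants are treated as
heterozygous in a diploid genome, so a tumor-derived molecule carries the
variant allele with probability tf/2. Variant selection in such assays
prioritizes high-allele-frequency (clonal, likely heterozygous) sites,
which motivates the convention; it is configurable through the per-site
multiplicity implicit in the 2(k − λ)/N estimator. Sums of independent
Poissons are Poisson, so the aggregate k ~ Poisson(N·tf/2 + λ) exactly —
the generative model and the detection null coincide, and moment-estimator
recovery is exact in expectation.

**Detection** is a one-tailed exact Poisson test, p = P(X ≥ k | λ), with
positivity at p ≤ α = 0.001. The exact tail (never a normal approximation)
matters because ultrasensitive samples have k of order 1–10. k = 0 gives
p = 1. With λ = 0 the tail is degenerate; p-values are clamped to the
smallest positive double so they remain in (0, 1].

**Quantification**: PPM = 10⁶ · max(0, 2(k − λ)/N). Background subtraction
is on by default and toggleable. Undetected samples report PPM = 0 —
negativity is treated as a state by every downstream rule (clearance,
running minimum, clustering), so a sub-threshold point estimate is never
propagated.

**Limit of detection**: the smallest tumor fraction detected with
probability ≥ 0.95 at α = 0.001. Compute k_crit = min{k : P(X ≥ k | λ) ≤ α},
then the smallest total mean μ* ≥ λ with P(X ≥ k_crit | μ*) ≥ 0.95 by
bisection (relative tolerance 10⁻⁶; the tail probability is strictly
increasing in μ), and LOD = 10⁶·2(μ* − λ)/N. LOD definitions vary across
assays (power level, background handling), so the power is an explicit
parameter; with the default simulated panel (λ ≈ 7.7 over N ≈ 3.6·10⁶) the
median per-sample LOD comes out ≈ 10 PPM, qualitatively in the few-PPM
ultrasensitive regime rather than matched to any particular assay.

**Sensitivity floor**: `apply_detection_floor` reclassifies calls with
PPM strictly below 100 as undetected (PPM 0), emulating a conventional
detection threshold; 100 PPM itself survives.

## Molecular response rules

Timelines are day-stamped calls with treatment start at day 0.

* Baseline = first sample at/after day 0; follow-up = earliest later
  sample whose gap from baseline lies in [10, 45] days (the observed
  schedule: first draw ~day 4, second ~23 days later). Patients missing
  either are *not evaluable* for mR and excluded from mR survival analyses.
* **mR** at threshold θ ∈ {0.3, 0.5, 0.75}: response iff the baseline is
  positive and 1 − PPM_fu/PPM_base > θ (strict), or both samples are
  negative (sustained negativity). A negative baseline followed by a
  positive follow-up is adverse: no response. Response is monotone in θ.
* **mCR**: any undetected sample strictly after baseline. Clearance must be
  demonstrated on treatment, so a lone baseline is never mCR; a
  never-detected patient with follow-ups qualifies (flag
  `mcr_include_never_detected=False` additionally requires at least one
  detected sample).
* **mPD**: for each sample after the first, with m the minimum PPM over all
  strictly earlier samples: flag iff the sample is detected and either
  PPM ≥ 1.3·m (m > 0) or PPM > 0 after clearance (m = 0). Requiring a
  positive detection call keeps background noise at negative timepoints
  from triggering progression (`mpd_require_detected` exposes the choice).
  The mR/mPD comparison asymmetry (strict > vs inclusive ≥) is deliberate
  and kept verbatim from the definitions.
* **Lead time** = imaging-progression day − first mPD day; negative when
  molecular progression trails imaging.

All labels are invariant to rescaling every PPM by a positive constant.

## Trajectory clustering

Each patient with ≥ 2 samples becomes a univariate series of
log₁₀(PPM + 1), 0 at negative timepoints. Series are unequal-length and
irregularly sampled, so the pairwise distance is dynamic time warping
(absolute-difference local cost, full window); an interpolate-then-
Euclidean alternative is available behind `metric="interp_euclidean"` for
robustness checks. The distance matrix feeds average-linkage (UPGMA)
agglomerative clustering cut at k = 2 — Ward linkage is avoided because
DTW is not a Euclidean embedding. An all-zero distance matrix is reported
as a degenerate single-cluster partition rather than an arbitrary split.

Risk labels use ctDNA features only: the cluster with the greater median
baseline level is *high*; ties break toward the lower clearance fraction.
Clinical data never enter the clustering code path. The 100 PPM sensitivity
analysis floors the calls and re-runs the identical pipeline; when group
structure lives below 100 PPM, flooring collapses it (adjusted Rand index
against the generating archetypes drops from ≥ 0.7 to ≈ 0).

## Survival statistics

Kaplan–Meier, Cox and log-rank go through lifelines; Cox uses Efron tie
handling (the R `survival` default) and Wald CIs/p-values, with convergence
or separation warnings surfaced as a `flagged` result. The Freeman–Halton
exact test enumerates all r×c tables with the observed margins and sums the
multivariate hypergeometric probabilities not exceeding the observed
table's (relative fp tolerance 10⁻⁷), capped at margin totals of 200 —
exhaustive and exact at cohort scale, where the 2×3 response-by-BOR table
evaluates in milliseconds. Time-dependent ROC uses the cumulative-case /
dynamic-control AUC with KM-based inverse-probability-of-censoring weights
(scikit-survival); with no censoring it reduces to the empirical rank AUC
of the binary outcome at the horizon. TMB is dichotomized at 10
mutations/Mb and MSI at MSI-H vs MSS in the multivariable model.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
consensus-molecule level (no reads, no sequences):

* **Panel**: per-site error rates log-uniform on [10⁻⁷, 10⁻⁵]; depths
  Gamma(shape 10) with mean 2,000 molecules/site; 1,800 sites. These yield
  N ≈ 3.6·10⁶ and λ ≈ 7.7 per sample.
* **Archetypes** (baseline log₁₀PPM ~ Normal; per-sample lognormal
  biological noise; per-day rates):
  clearance (baseline ~250 PPM, decay 0.10/d, true clearance at day
  40–80, hazard ×0.15), partial response (~560 PPM, decay to a 15%
  plateau, ×0.5), persistence (~3,160 PPM, drift +0.006/d, noise σ 0.35,
  ×1.5), regrowth (~1,260 PPM, dip then +0.02/d regrowth, ×2.5). The
  default mix (0.35/0.30/0.20/0.15) makes best overall response land near
  37% PR / 53% SD / 11% PD and puts roughly a third of positive detections
  below 100 PPM, the regime the assay is built for.
* **Sampling schedule**: first draw ~day 4 (±3), second +23 d (±5), then
  every 42 d (±5); 4–9 samples per patient.
* **Clinical linkage**: PFS ~ Exponential with hazard (ln2/180 d)·multiplier,
  OS = PFS + an exponential tail, administrative censoring Uniform(365,
  1095) d. Hazards depend only on the hidden archetype — never on the noisy
  measurements — so configured hazard ratios are recoverable by Cox
  regression (within ~30% at n = 500). TMB is lognormal with median
  4.27 mut/Mb; 10% of patients are MSI-H.

What the generator does **not** emulate: pseudoprogression, cfDNA input
variation, panel dropout/resampling, correlated per-site errors,
informative censoring, or any dependence of sampling on clinical events.
Passing tests therefore demonstrate internal consistency of the analysis
under its own model, not performance on real plasma data.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 39–200 patients (500 for
hazard-ratio recovery), 10⁵ aggregate null replicates for the type-I error
check, and 10⁴ replicates for count-mean recovery; a full 200-patient
pipeline completes in seconds. Null-panel replication exploits the
Poisson aggregate identity (the sum of per-site background draws is
Poisson(λ)), which is exact, not an approximation. Tie-breaks: equal-risk
clusterings pick cluster 0 deterministically; identical survival groups
short-circuit the log-rank statistic to 0 to avoid 0/0. Degenerate inputs
(single-sample timelines, empty call lists, zero margins) return defined
values rather than raising wherever a definition exists.

## Deposited-data adapter

`load_deposited` maps a locally supplied directory of processed tables
(per-sample ctDNA levels; per-patient clinical outcomes) onto the internal
schemas by recognizing common column spellings, filling assay-internal
fields (p-value, LOD) with NaN, and ignoring unmapped columns. It performs
no network access; the exact published column layout could not be
inspected when the adapter was written, so the candidate list is the
mapping's single point of maintenance.
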