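# Methods

## Measurement model (synthetic cohorts)

One e-nose breath-print is a conductivity tensor `G ∈ R^{36×64×3}`
(temperature samples × heat-cool cycles × sensors). The hotplates sweep
260–340 °C; we model the sweep as 36 samples on a uniform temperature grid.
The record length (64 × 36 points per sensor) is the constraint we match
exactly; how the device's 32 heating steps map onto 36 recorded samples is
a hardware detail we deliberately abstract as "the sampled sweep".

The generator draws, per subject,

    log conc_v ~ Normal(mu_v(class, subsite), subject_sd),  v = 1..8

and evaluates

    G[t,c,s] = offset[d,s] * baseline[s,t] * (1 + Σ_v kernel[s,v,t] conc_v)
               * (1 + drift)^c * exp(sigma_n eps[t,c,s] - sigma_n²/2).

Every factor is positive, so conductivities are strictly positive — the
same invariant the file reader enforces.

Design choices, all made for positivity and smoothness resembling
metal-oxide redox response curves (no generative model is published for
the device):

- **baseline**: per-sensor Gaussian bump on a unit offset, peak positions
  spread over the grid (sensors differ, as real sensor chemistries do);
- **kernels**: Gaussian response curves (width 18 °C, amplitude 0.05) with
  per-(sensor, compound) peak temperatures spread deterministically over
  the sweep, so the 8 virtual compounds are spectrally distinguishable;
- **drift**: geometric per-cycle trend, default rate 0.002 (≈ +13 % over a
  measurement) — sensors warm up and foul slowly;
- **noise**: multiplicative lognormal, sigma 0.05 (mean-one), a generic
  model for proportional sensor noise;
- **device effects**: per-(device, sensor) multiplicative offsets,
  lognormal with sigma 0.05, frozen constants of the model (not per-cohort
  randomness). This is the simplest mechanism that makes the per-device
  class-balance requirement consequential.

**Class effect.** `effect_size` is the per-compound standardized shift
(Cohen's d): case mean log-concentrations are
`mu_ctrl + effect_size * subject_sd * pattern` with `pattern` a ±1 vector.
The default pattern is shared across subsites; with
`subsite_specific=True` each subsite uses one of three mutually orthogonal
±1 Hadamard rows, making the pooled case class heterogeneous while keeping
every subsite equally far (in Mahalanobis distance) from controls. The
default effect size is 2.0 — a strongly separable regime for verifying
signal recovery; 0.0 gives exact class exchangeability for null
calibration. The subsite-comparison experiments run at effect size 1.0,
the moderate-separability regime in which pooled-case heterogeneity
measurably hurts the all-subsites model, which is the phenomenon those
experiments probe.

**Cohort composition** defaults to the study scale: 37 oral + 34
oropharynx + 20 glottis cases and 72 controls over 4 devices, devices
assigned round-robin within class (so the ≥5-per-class-per-device rule
holds by construction and infeasible designs fail early with the violated
constraint named). The smoking flag is drawn at class-dependent prevalence
(49/91 cases, 26/72 controls) but is not wired into the sensor model; it
exists so confounding experiments can be added without changing the data
model.

**What the generator does not emulate**: adsorption-tube chemistry and
filtering hardware, fasting/medication effects, non-stationary
environmental backgrounds, sensor aging across months, or realistic VOC
identities. Passing tests therefore show that the analysis chain recovers
the statistical structure it assumes — not that the device separates real
patients.

## Tucker3 compression

Cohorts are stacked as `X ∈ R^{n×108×64}`, mode 2 concatenating the three
sensors' temperature samples sensor-major. The decomposition is fitted by
HOOI initialised from the truncated HOSVD; factor updates use the Gram
eigenproblem of the partially contracted unfoldings. Numerical choices:

- **sign convention**: each factor column is oriented so its
  largest-magnitude entry is positive (ties: lowest index), making factors
  reproducible across runs and platforms;
- **convergence**: stop when the explained-variance fit improves by less
  than 1e-6 between sweeps, cap 100 sweeps; fit is `||core||²/||X||²`,
  non-decreasing across sweeps by construction (each update maximises the
  core norm given the other factors);
- **full-rank modes** keep the identity factor — any orthonormal square
  basis is optimal and the identity is deterministic. The subject mode is
  always full rank (`r1 = n`): subjects must stay individually recoverable
  as feature vectors;
- **rank selection** (`choose_ranks`): smallest `(r2, r3)` on the lattice
  {1, 2, 3, 4, 6, 8, 12, 16} (plus the mode extent when ≤ 16), ordered by
  `r2*r3` then lexicographically, whose *truncated-HOSVD* fit reaches the
  target (default 0.99). The HOSVD fits for every lattice point come from
  one cumulative energy table of the full HOSVD core, and HOOI can only
  improve on HOSVD, so the first point passing the screen meets the target
  without fitting HOOI per lattice point. If no point reaches the target
  (typical for fiber-standardized noisy data, where no low-rank model
  explains 99 % of variance) the lattice maximum (16, 16) is used and
  flagged.

Held-out measurements are projected with training-fold factors and the
training-fold scaling record only; the Tucker model is refit inside every
cross-validation training fold. Whether the original proprietary software
refit per fold is unknown; leakage-free is the defensible default, and a
single-fit mode is available by fitting `TuckerCompressor` once and reusing
it.

## Scaling options and the scoring network

Four scaling options form the candidate grid, parameters always estimated
on training data only: `none`; `zscore_fiber` (standardises each
(temperature-sensor, cycle) fiber across measurements — applied to the
stacked tensor *before* the Tucker fit, since it is a fiber operation;
zero-variance fibers map to 0); `minmax_feature` and
`unit_norm_per_measurement` (applied to the post-Tucker feature matrix).
Fiber standardisation is the option that usually wins model selection on
raw conductivity data: the common baseline curve dominates raw variance,
and removing it lets the class signal drive the decomposition.

The network is deliberately minimal: one hidden layer (default 8 tanh
units), a single tanh output — so scores lie in (−1, 1) by construction —
trained by full-batch Adam (default 300 epochs, step 0.02, L2 penalty
1e-3) on squared error against ±1 labels. No early stopping: a fixed epoch
budget keeps training deterministic given the seed. Class imbalance is not
reweighted by default. Divergence (non-finite loss) raises with a
suggestion to lower the step size.

## Validation and reporting

- **Folds**: stratified leave-10%-out (10 folds; leave-one-out below
  n = 10 with a warning). Each class's shuffled members are dealt to folds
  through one running cursor, so per-fold totals *and* per-fold class
  counts are within one of even — stratification prevents single-class
  folds in the 20-case glottis model.
- **ROC/AUC**: curve over all distinct cut-points, ties collapsed to one
  cut-point (diagonal segment); trapezoidal AUC, hence exactly the
  Mann-Whitney statistic with ties counted ½.
- **Threshold**: candidates are midpoints of adjacent distinct sorted
  scores plus the endpoints ±1; rule `score > t → positive` (a score equal
  to the threshold is negative — the boundary case is stated explicitly);
  accuracy maximised, ties broken by Youden's J then the smallest
  threshold. Selection happens on *pooled* out-of-fold scores, matching
  how a single per-model threshold is reported in practice; the optimism
  this introduces is recorded in every report's `note` field.
- **Metrics**: percentages rounded half-up to whole percent for display,
  full-precision fractions retained; zero-denominator rates are flagged
  undefined rather than reported as 0. No multiple-testing correction is
  applied across the four models; reports say so.
- **Model selection**: highest cross-validated accuracy; ties broken by
  AUC, then fewer hidden units, then the canonical scaling order.

## Problem sizes

Unit and property tests run on small random tensors and compact cohorts
(tens of subjects). The end-to-end checks use the full 163-subject design:
signal recovery on one strong-effect cohort, null calibration over 20
replicate zero-effect cohorts, and the subsite-vs-pooled comparison over
10 replicate subsite-specific cohorts — sizes at which the Monte Carlo
bands in the tests are stable while a full run stays around 20 seconds.

## Known limitations

- The proprietary analysis software's network architecture, Tucker ranks,
  scaling set and training schedule are unpublished; this package fixes
  defensible defaults and exposes them as parameters. Published thresholds
  and metric tables are therefore not reproducible quantities; the tests
  verify recovery of planted structure and exact agreement with
  independent oracles instead.
- Pooled post-hoc threshold selection inflates accuracy relative to
  fold-internal thresholding; it is kept because it mirrors the reporting
  convention, and is flagged in every report.
- The generator's lognormal/Gaussian forms are conventional, not
  physically derived; conclusions about real breath data require real
  measurements ingested through `read_cohort`.
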