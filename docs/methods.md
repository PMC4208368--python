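# Methods

This note documents the models, conventions and design choices behind the
`fallrisk` package: a pipeline from raw biomechanical signals to a
faller/non-faller classification for cohorts of older adults, together with
the synthetic cohort generator used to exercise it end to end.

## Pipeline overview

1. **Feature extraction** (`fallrisk.features`). Raw trials in three
   functional domains are reduced to a battery of 92 scalar measures per
   subject:
   * *Force control* (FC, 20 measures): maximum voluntary isometric
     contraction (MVIC, best of three peak torques) for knee extensors and
     ankle plantarflexors, and mean/SD/CV of the torque trace while tracking
     submaximal targets (constant 15%, constant 20%, ramped 15–20% of MVIC).
     Torque traces lose their first 7 s and last 2 s (initiation/termination
     transients) and are low-pass filtered (4th-order zero-phase Butterworth,
     25 Hz) before summary statistics.
   * *Quiet standing* (QS, 28 measures): from 30 s centre-of-pressure traces
     (120 Hz, eyes open QEO / closed QEC, three repetitions averaged), after
     trimming 2 s at both ends and 2nd-order zero-phase Butterworth filtering
     at 5 Hz: mean and RMS distance, mean velocity and mean frequency
     (resultant plus AP/ML components), swept sway area per second, and the
     95% confidence-ellipse area
     `2π·F(0.95; 2, n−2)·sqrt(s_AP² s_ML² − s_APML²)`. Directional mean
     frequency uses the `VEL/(4·DIST)` oscillation convention and the
     resultant uses the `VEL/(2π·DIST)` rotation convention; whether the
     original instrumentation used the same directional convention is not
     decidable from its description, so the choice is fixed here and
     documented.
   * *Gait* (GA, 44 measures): marker trajectories of eight foot markers
     (heel, first/fifth metatarsal heads, base of second/third metatarsus per
     foot) are filtered (4th-order zero-phase Butterworth, 25 Hz); a
     foot-velocity event detector locates heel strikes and toe-offs; stride,
     stance, swing and double-support times, stride length, step length,
     step width, cadence and foot clearance follow; the first and last
     stride of each walk are removed; mean, SD and CV are computed over the
     strides pooled across (at least six) walks. CVs are dimensionless
     throughout (percent only at presentation).

2. **Factor reduction** (`fallrisk.factors`). Measures are standardized to
   Z-scores per column over observed values; missing cells become 0 (the
   sample mean) and the imputation mask is retained. The iterative loop then
   (i) removes measures with sampling adequacy (MSA) below 0.5, (ii)
   eigendecomposes the correlation matrix, retains components with
   eigenvalues strictly greater than 1 (Kaiser), applies Kaiser-normalized
   VARIMAX, and (iii) removes measures with absolute rotated loadings above
   0.4 on two or more components (complex structure), repeating until an
   iteration removes nothing. Component scores use the regression method
   `W = R⁻¹Λ`. Interpretive component labels (static balance, temporal gait,
   spatial gait, temporal variability left/right, spatial variability,
   dynamic balance) are assigned post hoc from the dominant measure domain
   and never enter any computation.

3. **Classification** (`fallrisk.logistic`). Binary logistic regression of
   retrospective fall status (faller = 1) on the component scores, fit by
   Newton/IRLS maximum likelihood (via statsmodels) with standard errors
   from the observed information. The coefficient table reports β, s.e.,
   Wald = (β/s.e.)², the χ²(1) p-value and exp(β). Predictors with p < 0.1
   are refit as the reduced model, which classifies at probability threshold
   0.5 (configurable; the full model can classify instead). Diagnostics:
   Nagelkerke R² and a decile Hosmer–Lemeshow test (bins merge on zero
   expected counts, reducing the degrees of freedom). Classification is
   in-sample, matching the retrospective design; reports flag this.

4. **Evaluation** (`fallrisk.evaluate`). Confusion matrix with faller as the
   positive class; sensitivity/specificity/PPV/NPV in percent, rounded half
   away from zero only at presentation. Group comparisons use Welch's
   two-sample test between fallers and the non-faller group excluding
   prospective first-time fallers (NF′); the first-time-faller (FTF) subset
   is summarized descriptively only (six subjects cannot support a test) and
   the report records whether the FTF mean lies between the F and NF′ means.

## Synthetic cohort generator

No raw data from the original laboratory study are public, so the generator
(`fallrisk.synthetic`) emulates the study design: 38 fallers and 42
non-fallers (six of them prospective first-time fallers), each with six
walks over a 10 m walkway (markers at 100 samples/s — a typical rate for
this camera class; the study does not state one), three 30 s CoP trials per
eyes condition at 120 Hz, and three torque trials per joint and target plus
three MVIC attempts.

**Latent structure.** Each subject carries a seven-dimensional latent vector
over the functional domains listed above, drawn from a group-specific normal
with identity covariance (truncated at ±3 SD). Group separation is confined
to the domains the reference analysis found discriminative: spatial gait
(standardized difference −0.85; fallers take shorter, lower strides),
temporal variability left (+0.60) and right (+0.45); all other domains
overlap completely. First-time fallers draw their latents midway between the
group means with the same covariance. Latent values map to physical
parameters log-linearly (e.g. stride length `1.22·exp(0.065·s)` m, stride
time `1.07·exp(0.045·g)` s, per-foot stride-time SD `0.021·exp(0.45·v)` s,
QEC sway amplitude `8.5·exp(0.30·b)` mm), with small subject-specific jitter
per measure so that no two measures are exact duplicates.

Three generator choices deserve emphasis:

* *Sway frequency as the seventh domain.* Per-cycle "phase" noise cannot
  drive double-support variability without also contaminating the
  contralateral foot's stride times (any jitter of a strike time is stride
  timing), so a gait-timing quantity cannot host a seventh separable domain
  at these trial counts. The generator instead assigns the seventh domain to
  the bandwidth of the CoP process (how fast the centre of pressure is
  steered about its mean), independent of sway magnitude — a recognized
  second dimension of posturography. Its component is labelled *dynamic
  balance*; double-support variability remains a bilateral mixture of both
  feet's timing noise and is expected to prune as complex structure, as many
  measures did in the reference analysis.
* *No strength domain.* MVIC and the force-tracking means are deterministic
  mixtures of the spatial-gait, temporal-gait and balance latents plus trial
  noise (stronger subjects walk faster with longer strides), and force
  steadiness at each target level mixes a different pair of
  balance/variability domains. Seven domains therefore span the entire
  battery, and the force-control block carries no unique common factor: its
  measures load moderately on two or more components and are removed by the
  complex-structure rule, mirroring the exclusion of muscular-control
  measures in the reference analysis. This is a deliberate simplification —
  real strength has unique variance — adopted so that the planted component
  count is exactly seven.
* *Drift-free gait clock.* Strike times are i.i.d. jitters around a regular
  clock (per-foot SD σ/√2, so stride times have SD σ with the lag-one
  negative correlation characteristic of event-differenced series); strike
  positions accumulate i.i.d. stride-length increments; the contralateral
  foot lands midway (in space) between surrounding ipsilateral strikes. Every
  walk carries planted ground truth (event times/positions, per-stride
  clearance) for oracle testing. The swing-phase vertical profile rises with
  peak upward velocity at toe-off and ends its final descent with peak
  downward velocity exactly at touchdown, which is the signature the
  foot-velocity detector keys on; noise-free recovery within one sample is
  the detector's conformance bar (the velocity extrema themselves shift by
  1–2 samples under zero-phase filtering, so events are fixed at the
  adjacent stance boundaries).

**Two sampling paths.** `generate_cohort` synthesizes raw signals;
`sample_cohort_features` summarizes the identical cycle-level draws directly
into the feature table (sway and torque traces are still synthesized — they
are cheap — but marker synthesis and event detection are skipped). The two
paths agree to event-quantization accuracy (means within a few percent,
SD-type measures within ±1 sample of jitter), which a pipeline test checks.
Many-seed Monte-Carlo checks use the fast path; the flagship run and the
acceptance script's headline numbers use the raw-signal path.

**What the generator does not emulate.** Raw-signal distributions are
calibrated to directionality and physiological plausibility, not to the
study's unpublished magnitudes; there are no soft-tissue artifacts, no
marker occlusions, no anticipatory gait adjustments near the walkway ends,
no fatigue or learning across trials, and the latent covariance is identity
(real functional domains correlate). Passing tests therefore demonstrate
that the pipeline recovers a known structure of this kind — not that the
original study's specific loadings, KMO (0.714), Nagelkerke R² (0.26) or
Hosmer–Lemeshow p (0.44) would be reproduced, which requires the original
cohort. Only the closed-form quantities (the confusion-matrix percentages,
the exp(β) column, the exclusion arithmetic, the variance-percentage total)
are exact reproductions from printed inputs.

## Numerical conventions

* **Filters**: "zero phase" means design at the stated order and apply
  forward–backward (`sosfiltfilt`), giving the squared magnitude response
  (gain 0.5 at the cutoff).
* **Correlation-matrix inversion**: a ridge `λ = 1e-8·trace(R)/p` replaces a
  singular/ill-conditioned inverse, with a warning, both for anti-image
  partials and regression score weights.
* **MSA in the rank-deficient regime**: with 92 measures and 80 subjects the
  sample correlation matrix is singular and anti-image partials are
  artifacts of sampling rank, not of shared variance (experiments show
  entire strongly-correlated blocks receiving MSA ≈ 0.3 at p ≈ 0.9n). The
  iterative loop therefore suspends MSA pruning while p > 0.6n; Kaiser
  retention plus complex-structure pruning shrink the battery first, and MSA
  pruning engages once well-posed. The final solution always reports
  per-measure MSA and the overall KMO (NaN when never well-posed). How the
  original SPSS-based procedure behaved on its singular 80 × 92 matrix is
  not reconstructible from its description; the iteration log makes this
  package's convention auditable.
* **VARIMAX**: pairwise Jacobi sweeps with the closed-form rotation angle,
  Kaiser row-normalization, convergence when a sweep improves the criterion
  by less than 1e-10 (max 1000 sweeps); monotone by construction. Sign
  convention: each component's largest-magnitude loading is positive;
  components are ordered by post-rotation variance explained.
* **Kaiser rule**: strictly greater than 1; eigenvalues exactly 1 (e.g.
  perfectly orthogonal columns) are not retained.
* **Hosmer–Lemeshow**: deciles of risk with ties kept together; on cohorts
  smaller than 30 the pipeline uses `min(10, max(3, n/3))` bins.
* **Rounding**: half away from zero, presentation layer only (this is what
  turns 73.68% and 76.19% into the printed 74% and 76%).
* **Determinism**: all randomness flows from one seed through
  `numpy.random.SeedSequence` spawns (one child per subject, one integer
  stream per trial); identical configurations give byte-identical artifacts.

## Problem sizes

Default runs use the full 80-subject design. The component-count
Monte-Carlo uses 50 seeds of the feature-level path; directional
calibration checks use 12–20 seeds; the Hosmer–Lemeshow calibration uses
300 replicates at n = 300; logistic parameter recovery uses n = 2000.
These sizes give the binomial/asymptotic margins the assertions need while
keeping a full test run in single-digit minutes on one CPU.

## Known limitations

* The exact composition of the original 92-measure battery (its
  supplementary list is not available) is reconstructed here: 28 sway + 20
  force + 44 gait measures, shipped as `configs/registry_92.txt` and
  overridable; the reconstruction may differ from the original in which
  bilateral parameters carry CV entries.
* Whether the original "six iterations" counted adequacy and
  complex-structure passes separately is unknown; this implementation drops
  all offenders of both rules per iteration and logs each step.
* The force-plate reader (two plates → net CoP) is a convenience for real
  recordings and is untested against the original hardware's channel
  layout.
* In-sample classification overstates out-of-sample performance by design;
  no cross-validation is attempted because the reference design had none.
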