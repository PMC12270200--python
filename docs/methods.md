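# Methods

This note documents the models, the synthetic data, the numerical
choices, and the limits of what the test suite demonstrates.

## The screening pipeline

The pipeline is two-staged.  Stage one trains, per recording task
(finger tapping, smile, speech), a shallow dense network — one or two
hidden ReLU layers with dropout, sigmoid output, binary cross-entropy
loss — on that task's feature block.  Dropout stays active at inference
("MC dropout"): T = 30 stochastic forward passes give per-session samples
of the output probability, summarised as the mean p̄, the sample standard
deviation σ (the task's predictive uncertainty), and an empirical central
interval.  Stage two locks the task models and trains the fusion network
on sessions with all three blocks present: each block is projected
(linear → ReLU → MC dropout → layer normalisation) to a shared width, the
three tokens pass through scaled dot-product self-attention whose
post-softmax weight toward key *j* is multiplied by exp(−η·σⱼ) with rows
renormalised, and the contextualized vectors are concatenated with the
three task-level mean probabilities into a small sigmoid head.  At
prediction time the task-level statistics are computed once per session
and held fixed while the fusion stack runs its own T stochastic passes; a
verdict is withheld when the resulting 95% interval contains the decision
threshold.

Design points that were genuinely open, and the choices made:

- **Calibration formula.**  "Down-weight unreliable modalities" is
  implemented as post-softmax multiplicative damping exp(−η·σⱼ) with row
  renormalisation: monotone in σ, exactly neutral at η = 0 or equal
  sigmas, and spanning near-uniform to winner-take-all over the searched
  η range [0.1, 100].  The attention module is isolated so an alternative
  formula is a one-function swap.
- **What "uncertainty" is numerically.**  σⱼ is the standard deviation of
  task *j*'s MC sigmoid outputs, on the probability scale.
- **What the projections consume.**  The fusion projections take the
  preprocessed feature vectors (not task-model hidden activations); the
  task models contribute through their mean probabilities, concatenated
  into the head input (width 3·projection_dim + 3).
- **Intervals.**  Empirical 2.5/97.5 percentiles of the MC samples rather
  than a normal approximation — distribution-free, and the per-pass
  samples are retained on every prediction so any other convention can be
  recomputed after the fact.  When all passes agree the summary is forced
  exactly degenerate (σ = 0, interval a point).
- **Withheld sessions** are excluded from confusion-matrix metrics;
  coverage (fraction receiving a verdict) is always reported alongside.
  The decision threshold (0.5) and interval level (0.95) are exposed
  parameters.
- **Class imbalance** is handled by optional classic SMOTE before task
  training (k-NN convex interpolation among minority rows), not by loss
  re-weighting.  Only classic SMOTE is implemented; the variant name in
  the search space is an extension point.

The networks are implemented on a small numpy engine
(`pdscreen.nn`) with hand-written reverse-mode gradients — dense, ReLU,
inverted dropout, affine-free layer normalisation, stable
sigmoid/cross-entropy, SGD with momentum, AdamW, RMSprop, step and
plateau schedulers.  All gradients, including the path through the
modulated-attention renormalisation, are verified against central finite
differences in the test suite (median error ~1e-12; isolated larger
deviations at exact ReLU kinks are a finite-difference artifact, not a
gradient bug).  Dropout draws from a caller-owned generator, so every
stochastic pass is replayable.

## Cohort balancing

Balanced evaluation cohorts minimise the diversity loss
ℒ = Σₐ Σᵢ (Eᵢ − Oᵢ)²/Eᵢ over sex (50/50), ethnicity (45% white / 45%
non-white / 10% unknown) and age (45% under 50 / 45% over 50 / 10%
unknown), with expected counts Eᵢ = proportion × selection size.  The
genetic algorithm starts from a random selection with exact class counts
(50% PD by default), proposes one same-class swap per iteration, accepts
only strict loss decreases (so equal-loss swaps cannot cycle), and stops
a restart after `max_stale` (default 2,000) consecutive rejections — the
convergence criterion is otherwise unspecified, and a stall counter
bounds runtime while approximating "converged to a local optimum".  The
best of `restarts` (500 in the documented CLI default) is kept.  PD
status is held exact by construction and therefore not scored in the
loss.  Test and development sets are selected sequentially (test first,
then dev from the remainder), which guarantees participant-disjoint
splits.  On pools small enough to enumerate, the GA's best-of-restarts
matches exhaustive search exactly (verified in tests).

## The synthetic cohort generator

The generator emulates the *shape* of a multimodal remote-screening
study, not any real feature distribution:

- **Latent severity.**  Per participant, s ~ Normal(+1, 1) for PD and
  Normal(−1, 1) otherwise; sessions share s plus Normal(0, sd 0.25)
  jitter, giving within-participant correlation.  The jitter scale is
  read as a standard deviation: with sd 0.25 the session-level Bayes
  AUROC ceiling is ≈ 0.913, which keeps the generator consistent with
  the package's own fusion benchmarks (a variance reading would cap
  every classifier below 0.90 regardless of training).
- **Features.**  For modality m with effect size δₘ, the first
  `n_informative[m]` coordinates equal s·δₘ plus Normal(0, noise_sd²)
  noise; the rest are pure noise.  Class means of s are ±1, so an
  informative coordinate separates the classes by 2δₘ.  Defaults
  δ = (1.0, 0.5, 1.5) for tapping/smile/speech encode the empirical
  ordering speech > tapping > smile.  Informative-subspace sizes default
  to (65, 21, 256) of the (130, 42, 1024)-dimensional blocks: the tapping
  and smile blocks model *curated* clinical feature sets (about half
  informative), the speech block a distributed self-supervised embedding
  (about a quarter).  Under these defaults a plain logistic regression on
  the concatenated raw features reaches held-out AUROC ≈ 0.90, i.e. the
  synthetic task is hard but solvable, which is the regime the fusion
  benchmarks require.
- **Demographics** are drawn per attribute from configurable proportions
  (defaults resemble a large remote cohort: 52% female, ~11% non-white
  with many unknowns, older skew), including explicit "unknown" bins so
  the balancer's unknown subgroups are exercised.  Sex carries no unknown
  bin because the balancing targets score only male/female.
- **Stages, provenance, durations, missingness.**  A Hoehn–Yahr stage
  (1–3, by severity quantiles) is recorded for 31% of PD participants;
  57% of PD labels are marked clinically confirmed, the rest
  self-reported.  Task durations are Normal(30 s, 5 s) with a configurable
  fraction of ±5 sd outliers to exercise the 3-sigma filter.  Modality
  blocks are deleted independently at configurable rates, never leaving a
  session empty.
- **Reproducibility.**  One root seed; each participant draws from a
  child stream keyed by a stable hash of the participant id, so cohort
  size or insertion order never changes an individual's data.  Identical
  config + seed reproduces the serialized table byte for byte.

What passing tests on this generator do **not** show: robustness to the
correlated, heavy-tailed, non-stationary structure of real video/audio
features, to label noise in self-reported diagnoses, or to systematic
(non-random) missingness.  The Gaussian independent-noise model is a
stand-in and makes several benchmarks easier than reality would.

## Preprocessing

Duration filtering flags a session's task when its recording duration
deviates from the task mean by more than 3 sample standard deviations
(n−1 denominator), computed over the whole incoming table; flagged blocks
become missing downstream, and a session is excluded outright only when
no block survives.  Scalers (standardize / min-max) are fitted on
training rows only; constant columns map to 0.  Correlation-based
selection scans columns in file order and drops a column iff its |r| with
an already-kept column exceeds the threshold — deterministic and
idempotent; zero-variance columns correlate 0 with everything except an
identical constant duplicate (treated as |r| = 1).  No canonical
threshold exists; it is a configuration knob, off by default in the
pipeline.

## Evaluation statistics

Point metrics come from the standard 2×2 definitions with undefined
ratios reported as NaN (never 0).  AUROC uses the Mann–Whitney rank
identity with half-credit ties; AUPRC is step integration (average
precision).  Confidence intervals are percentile bootstrap (B = 1,000
default) — percentile rather than BCa because nothing in the reported
procedure requires bias correction; resamples on which a statistic is
undefined are redrawn and counted.  Metric comparisons use the two-sided
tie-corrected Mann–Whitney test on the bootstrap distributions.  The
two-proportion z test *refuses* (with an explicit error) when np < 5 or
n(1−p) < 5 in either group.  The Monte-Carlo chi-square test draws null
tables with fixed margins (`scipy.stats.random_table`) and uses the
add-one p estimator (1 + #{χ²_sim ≥ χ²_obs})/(reps + 1), so p > 0 always.
ECE uses 10 equal-width bins by default (no bin count is canonical).
Cohen's κ reports NaN when chance agreement is 1.  The misclassification
regression is a statsmodels logistic ML fit with Wald p-values and BH
adjustment across covariates; perfect separation and rank deficiency are
detected and refused rather than returning divergent estimates.
Evaluation is session-level; scipy/statsmodels/scikit-learn provide the
standard routines behind this module's surface, and every statistic is
cross-checked against an independent brute-force or closed-form oracle in
the tests.

## Problem sizes and runtime

The test suite and the acceptance script are sized for a single CPU: the
fusion benchmarks use 570-participant cohorts (two sessions each; 400
training participants = 800 complete training sessions, matching the
scale at which such fusion models are realistically trained) with task
nets of one 32-unit hidden layer (AdamW, 1e-3, 400 epochs) and a
128/32/16 fusion configuration (200 epochs); the withholding benchmark
uses 500 held-out sessions at half the effect sizes; GA checks run 500
restarts with a 300-rejection stall limit; bootstrap coverage runs 500
simulation replicates of B = 1,000.  The full suite runs in a few
minutes; `scripts/acceptance.py` in about half a minute.

## Known limitations

- The fusion model requires complete sessions; missing-modality fusion is
  out of scope.
- No post-hoc probability recalibration (temperature/Platt) is applied;
  Brier/ECE describe the raw fused probabilities.
- The hyperparameter search is plain random search over the published
  space; a Bayesian optimiser would find good configurations in fewer
  trials but adds a dependency without changing the contract.
- Only classic SMOTE is implemented among the oversampling variants.
- The numpy engine is CPU-only and sized for shallow networks; it is not
  a general deep-learning substrate.
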