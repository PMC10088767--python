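# Methods

`taskrel` analyses the psychometrics of cognitive-control task batteries:
four classic interference tasks (Stroop, AX-CPT, cued task switching,
Sternberg item recognition), each administered in three session variants
that bias subjects toward baseline, proactive, or reactive control, each
variant run twice (test and retest phases).  The individual-difference
measures of interest are reaction-time difference scores — interference
minus control condition — and the question is how reliably they rank
subjects.

## The hierarchical lognormal model

Correct-trial reaction times (seconds) for subject *i*, condition
*c* ∈ {control, interference} and phase *p* ∈ {test, retest} are modelled
as

    RT[i,c,p] ~ Lognormal(mu[i,c,p], exp(sigma[i,c,p]))

`mu` is the log-median; `exp(sigma)` is the trial-level sd of log RT.  The
lognormal form encodes the structural assumptions: RTs are positive,
right-skewed, vary around a subject-specific central tendency with
subject-specific trial-to-trial spread, and the RT sd grows linearly with
the RT mean at fixed `sigma` (sd/mean = sqrt(exp(exp(sigma)^2) − 1), the
"law of time" regularity of reaction-time data).

Each subject's four-vector of locations, and separately of log-spreads, is
drawn from a group-level multivariate normal with unknown mean vector and
covariance.  Covariances are separated into sd vectors and 4×4 correlation
matrices.  Priors: Normal(0, 1) on group means (sensible because fitting is
on the log-seconds scale; millisecond input is converted automatically),
Half-Normal(0, 1) on group sds, and a prior uniform over valid correlation
matrices.  Since the group model for `sigma` is normal and the individual
trial-level sd is `exp(sigma)`, the implied distribution of the sd itself
is lognormal and always positive.

The target quantity is the difference-score parameter

    delta[i,p] = mu[i,interference,p] − mu[i,control,p]

a log median ratio (not a millisecond difference; it is free of the
subject's overall speed).  Test–retest reliability is computed per MCMC
draw as the Pearson correlation over subjects between `delta[:,test]` and
`delta[:,retest]`, yielding a posterior distribution of reliabilities; we
report its mean, median and central 95% interval.  Draws in which either
phase has zero variance across subjects (up to rounding) are excluded and
counted.  The comparator throughout is the mean-point-estimate (MPE)
approach: per-subject condition-mean RTs, millisecond difference scores,
and their cross-phase Pearson correlation.

## Posterior computation

The sampler is a Metropolis-within-Gibbs scheme written for exactly this
model:

* **Individual locations** `mu[i,:]` and both **group mean vectors** have
  conjugate Gaussian full conditionals and are drawn exactly.
* **Individual log-spreads** `sigma[i,:]` get two moves per iteration: a
  joint random-walk preconditioned by (prior precision + Fisher
  information 2n per cell), and a Laplace-approximation independence
  proposal — the full conditional is log-concave, so a few batched Newton
  steps locate its mode/curvature and the resulting Gaussian proposal is
  accepted ~90% of the time.
* **Group covariances**: an inverse-Wishart independence proposal with
  df = N − d − 1, for which the Gaussian likelihood cancels exactly
  against the proposal kernel; the acceptance ratio reduces to the prior
  ratio (Half-Normal sds, uniform correlations, separation-strategy
  Jacobian).  Correlation matrices are parameterised by canonical partial
  correlations (vine construction), under which every point of (−1,1)^6 is
  positive definite and the uniform-over-matrices prior factorises into
  symmetric Beta densities.
* **Interweaving**: after the centered covariance update, non-centered
  sweeps re-propose (sd, partial correlation) components with the
  standardised subject effects held fixed, transporting every subject's
  parameters with the group scale.  This ancillarity–sufficiency
  interweaving breaks the covariance/effects coupling that otherwise
  dominates the autocorrelation; the spread side, which carries the least
  data information per cell, receives extra sweeps.

Step sizes adapt only during warmup (Robbins–Monro toward standard
acceptance targets).  The reference configuration is 3 chains × 3000 draws
after 1000 warmup iterations; the test suite uses a reduced configuration
(2 chains × 1000 draws after 500 warmup) whose posterior means agree with
the full configuration well inside Monte-Carlo error.  Convergence is
summarised per monitored scalar (individual `mu`/`sigma`, group means,
sds, correlation off-diagonals) by split-R-hat and bulk ESS via arviz; a
fit "passes" when max R-hat ≤ 1.01 and min ESS ≥ 400.  These thresholds
are package choices.  The slowest parameters (group sds/correlations of
the locations) have integrated autocorrelation times near 35, so clearing
the absolute ESS bar needs roughly 3 × 4–5k draws; posterior means are
stable far earlier.

Correctness was established by parameter recovery (group means inside
their 95% intervals; near-noiseless data recover the cohort delta
correlation to ±0.01) and by closed-form checks of the two-block
equilibrium: the within-draw scatter of delta equals the raw scatter minus
the analytic trial-noise variance, the shrinkage slope of posterior-mean
deltas on raw deltas matches the signal fraction, and the conditional
variance matches the harmonic combination of prior and data precision.

## Classical estimators

* **Permutation split-half**: each subject's trials are split into random
  halves, stratified within trial type so both halves support the
  difference score (an unstratified split can empty a condition); with odd
  counts the extra trial is assigned at random per permutation.  The index
  is computed per half, halves are Pearson-correlated across subjects,
  Spearman–Brown corrected (2r/(1+r)), and averaged over permutations
  (5000 by convention); the 2.5/97.5 permutation percentiles are reported
  as the interval.
* **ICC**: ICC(3,1) = (MSR − MSE)/(MSR + (k−1)MSE) (two-way mixed,
  consistency) and ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n)
  (two-way random, absolute agreement), with F-based confidence intervals
  (Satterthwaite df for the agreement form).  Values and intervals match
  pingouin's variance-components implementation to numerical precision.
  Note that ICC(3,1) ≥ ICC(2,1) is guaranteed only when both the subject
  and occasion variance components are non-negative; with MSC < MSE the
  agreement form can exceed the consistency form.
* **Preprocessing**: correct trials faster than 200 ms or slower than the
  cell mean + 3 sd (cell = subject × task × session × phase × trial type;
  statistics computed over the cell's correct trials including prospective
  outliers, single pass) are removed; a subject leaves a task when any
  cell retains less than half of its pre-trim correct trials (exactly half
  passes); a 40% error-rate cutoff per cell (errors / completed trials;
  non-responses count as neither) removes remaining low-effort subjects; a
  20–50% cutoff sweep is available as a utility.  Bivariate outlier
  screening at the correlation stage uses squared Mahalanobis distance
  against the chi-squared(1) 0.999 quantile (10.828), sample covariance
  with denominator n − 1, complete pairs only.
* **AX-CPT derived indices** use the standard signal-detection definitions
  with the 1/(2N) extreme-proportion adjustment: d′-context = z(AX hit
  rate) − z(BX false-alarm rate); A-cue bias = 0.5[z(H_AX) + z(FA_AY)]
  (sign convention: higher = stronger A-cue-driven target expectancy);
  PBI = (AY − BX)/(AY + BX) on mean RTs or on error rates with +0.5/+1
  additive smoothing.  Published battery studies defer these formulas to
  companion materials, so sign conventions may differ from any specific
  study's scripts.

## The synthetic-data generator

All stages are validated on simulated batteries with known ground truth;
the generator runs the hierarchical lognormal model forward.

Latent construction (exact formulas in `taskrel/synth.py`): a
battery-general factor, task factors, session factors and phase noise
combine so that the subject-level delta has cross-phase correlation
`rho_delta` (the target reliability, default 0.8), cross-session
correlation `rho_delta × within_task_coupling` (default coupling 0.6) and
cross-task correlation `rho_delta × cross_task_coupling` (default 0).
Base log-locations are a task-level trait shared only partially across
session variants (`base_session_stability`, default 0.6, since the
variants are distinct task contexts run in different weeks) with phase
jitter (`base_stability` 0.9); log-spreads have analogous
shared-plus-jitter structure.  Accuracy is Bernoulli per trial type,
independent of the RT channel (no speed–accuracy coupling), and a small
non-response rate can null out reaction times.

Default scales: trial-level sd of log RT `exp(sigma_mean)` = 0.13 (about
100 ms at the 750 ms Stroop base rate), between-subject delta sd 0.065
(about 50 ms), between-subject base sd 0.15, group effect magnitudes set
from published battery means (e.g. ~137 ms baseline Stroop effect) — these
are declared approximations, user-settable, with no claim of matching any
study population.  Battery-like trial counts include the deliberately
sparse Sternberg recent-negative cells (8 trials per subject in baseline
and proactive sessions; the scarcity moves to novel negatives in the
reactive variant).

`attenuation_oracle` predicts the expected MPE test–retest correlation:
r = cov(m_test, m_retest) / sqrt(prod_p [var(m_p) + v̄_p]), with the true
millisecond difference scores' moments evaluated over the subject
parameter distribution (large fixed-seed Monte Carlo) and the
trial-sampling variance of a mean analytic for the lognormal,
Var(RT)/n = (e^w − 1)e^{2mu+w}/n, w = exp(sigma)^2.  In the small-effect
linear regime this reduces to the familiar rho × signal/(signal + noise)
attenuation; the exact covariance form also captures two lognormal-scale
effects the linear formula misses — the mild inflation of millisecond
correlations by stable overall speed (effects are multiplicative in the
model) and the exp-transform distortion.  It matches the mean empirical
MPE correlation over hundreds of replicate studies to ±0.01.

What the generator does not emulate: practice and carry-over effects
across sessions, speed–accuracy trade-offs, strategy shifts, sequential
(trial-history) effects, and non-lognormal contamination (e.g. fast
guesses).  Passing parameter-recovery tests therefore shows the estimators
are correct and well-calibrated for data satisfying the model's own
assumptions — not that real batteries satisfy them.

## Problem sizes and numerical choices

Simulation scale in the test suite is chosen to keep the full run at
minutes while leaving conclusions stable: parameter recovery uses 60
subjects × 48 trials/cell (averaged over six replicate studies, because a
single cohort's realised delta correlation scatters around the population
value with sd ≈ 0.05 at n = 60, which would dominate a ±0.1 check of any
correct estimator); the dissociation battery uses 60 subjects × 12
trials/cell — the sparse regime in which trial noise visibly attenuates
MPE estimates while hierarchical pooling holds up.  Split-half checks use
a few hundred permutations (Monte-Carlo error of the permutation mean is
already ≪ 0.01 there); the 5000-permutation convention remains the
analysis-script default.

Degenerate inputs are handled explicitly: cells with fewer than two
correct trials get no slow trim (flagged); a zero between-subject delta
variance is flagged by the generator and yields an undefined (NaN)
attenuation prediction; zero-variance reliability draws are excluded and
counted; singular covariance in outlier screening raises with advice to
inspect the data; the hierarchical fit requires at least five subjects
with trials in all four cells and drops (and lists) incomplete subjects.

Known limitations: the model fits each task × session separately (no
information sharing across variants or tasks — a single all-encompassing
model is out of scope); the accuracy channel is summarised classically
only; the uniform correlation-matrix prior mildly shrinks very high delta
correlations at small n (the recovery bias is about −0.02 to −0.06 at 60
subjects × 48 trials); reliability posterior means, not full decision
analyses, are reported.
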