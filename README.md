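# taskrel — reliability analysis of cognitive-control task batteries

Experimental interference tasks (Stroop, AX-CPT, cued task switching,
Sternberg item recognition) measure cognitive control through difference
scores — interference minus control reaction time.  Used as individual-
difference measures, those scores are notoriously unreliable: the trial
noise that experimentalists average away attenuates the correlations that
differential psychologists need ("the reliability paradox").  `taskrel`
implements, as a tested pipeline over tidy trial tables, both sides of
that argument for a battery of four tasks × three control-mode session
variants (baseline / proactive / reactive) × two phases (test / retest):

* trial- and subject-level preprocessing (200 ms floor, mean + 3 sd slow
  trim per subject × trial-type cell, retention and error-rate criteria,
  Mahalanobis bivariate outlier screening);
* classical psychometrics: permutation split-half with Spearman–Brown
  correction, and Shrout–Fleiss ICC(2,1) / ICC(3,1) test–retest
  reliability with F-based confidence intervals;
* a hierarchical Bayesian lognormal model of trial-level RTs,

      RT[i,c,p] ~ Lognormal(mu[i,c,p], exp(sigma[i,c,p]))
      mu[i,:] ~ MVNormal(mu_mean, S_mu),  sigma[i,:] ~ MVNormal(sigma_mean, S_sigma)

  with Normal(0,1) / Half-Normal(0,1) / uniform-correlation priors, fitted
  by a purpose-built Metropolis-within-Gibbs sampler; the difference-score
  parameter delta[i,p] = mu[i,interference,p] − mu[i,control,p] yields,
  via per-draw Pearson correlation of delta across phases, a posterior
  distribution of test–retest reliability;
* correlation analyses comparing mean-point-estimate (MPE) and
  hierarchical (HBM) effect estimates within and between tasks, the
  reliability-vs-correlation pattern similarity (Fisher r-to-z), and a
  paired Wilcoxon contrast;
* a synthetic battery generator with known ground truth (controllable
  cross-phase delta correlation = true reliability, within- and cross-task
  coupling, trial counts, error rates), plus an analytic attenuation
  oracle for the MPE correlation — so every stage is verifiable by
  parameter recovery.

See `docs/methods.md` for the model, sampler, estimator conventions and
generator assumptions.

## Worked example

The analysis is a numbered pipeline; each script prints what it found and
writes tables under `results/` (big intermediates go to `scratch/`):

```
python analysis/01_simulate_battery.py          # 120-subject battery, seed 42
python analysis/02_preprocess.py
python analysis/03_classical_reliability.py
python analysis/04_hbm_reliability.py
python analysis/05_correlations.py
```

`02_preprocess.py` prints, for the simulated battery:

```
fraction of correct RT trials trimmed, per task:
  axcpt      0.135%
  cuedts     0.258%
  sternberg  0.137%
  stroop     0.262%
subjects removed: 16 task-level exclusions
task       reason
axcpt      error_rate_cutoff    10
sternberg  error_rate_cutoff     6
```

(the 40% cutoff bites in the tasks whose hard trial types have the highest
planted error rates; the sweep it also prints shows a 20% cutoff would
remove most of the cohort, a 50% cutoff almost nobody).

`03_classical_reliability.py` produces the classical table; e.g. the
baseline session rows:

```
 session         measure  split_half  icc21  icc31    mean   n
baseline   stroop_effect       0.846  0.707  0.708 137.975 120
baseline bx_interference       0.610  0.506  0.503  78.108 110
baseline            trce       0.829  0.634  0.633  73.723 120
baseline  recency_effect       0.621  0.503  0.501 110.029 114
```

Split-half (internal consistency) sits well above the ICCs: single-session
indices cohere, but cross-phase stability is attenuated by trial noise.
The generating cross-phase delta correlation is 0.8, so even ICC ≈ 0.5–0.7
understates the true stability of the sparse-cell measures.

`04_hbm_reliability.py` fits the hierarchical model per task × session and
prints the posterior reliability next to the MPE Pearson comparator
(excerpt from the run that produced `results/04_hbm_reliability.csv`; the
reduced 2-chain × 1000-draw configuration, which the script flags as below
the strict ESS bar — posterior means are stable, rerun with
`--chains 3 --warmup 1000 --draws 3000` for publication-grade diagnostics):

```
     task   session  hbm_mean  hbm_ci_low  hbm_ci_high  mpe_r   n
   stroop  baseline     0.843       0.758        0.915  0.708 120
sternberg  baseline     0.741       0.523        0.924  0.502 114
      ...
mean HBM reliability 0.76 vs mean MPE Pearson r 0.57
```

The hierarchical estimates sit near the generating 0.8 and exceed the MPE
correlation in every cell — most strongly in the 8-trial Sternberg cells,
where averaging has the least to work with.  `05_correlations.py` then
prints the dissociation:

```
within-task correlations (mean over task x session pair):
  MPE +0.32   HBM +0.38   Wilcoxon signed-rank p = 0.004
between-task correlations (mean over session x task pair):
  MPE +0.03   HBM +0.02
pattern similarity of reliabilities and within-task correlations (r-to-z scale):
  MPE +0.29   HBM +0.48
```

Within-task correlations rise under hierarchical estimation while the
(truly zero-coupled) between-task correlations stay near zero for both
estimate sets, and correlation strength tracks reliability.

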