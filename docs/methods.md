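# Methods

`multitrial` implements a two-stage, individual-participant-data pooled
analysis of multisite randomized trials with a binary endpoint, together
with the synthetic-data generator used to exercise it. The motivating
setting is a collaborative of three jail-based trials of medication for
opioid use disorder (MOUD) — extended-release naltrexone in two studies,
interim methadone in one — against an enhanced treatment-as-usual (ETAU)
control, with a medication-plus-patient-navigation arm in two of the three
studies. The endpoint is a binary flag for meeting current DSM-5 OUD
criteria six months after release.

## Cohort rules

Two fixed-order pre-analysis steps produce the analytic sample:

1. **Post-randomization exclusions.** Participants transferred to prison,
   incarcerated at the time of their 6-month follow-up window, or deceased
   are removed, with CONSORT-style per-study, per-reason accounting.
   Deceased participants are excluded rather than imputed: the worst-case
   imputation rule applies only to people *alive and in the community*.
2. **Missing-as-positive imputation.** Any remaining missing outcome is set
   to positive and flagged. This is a deliberately conservative single
   imputation: it biases against the treatment whenever missingness is
   nondifferential or treatment-favoring, and it makes the observed outcome
   prevalence an upper bound on the complete-case prevalence (tested as an
   invariant: post-imputation prevalence >= complete-case prevalence, with
   equality iff nothing was missing).

Running the two steps a second time is a no-op; the order is part of the
contract.

## Estimation

**Stage 1.** Within each study, a logistic model of the outcome on a
treatment indicator plus baseline covariates: age (centered at the study
mean — stabilizes the intercept without changing the treatment
coefficient), sex, race (two dummies, Black reference), housing status and
any prior cocaine/amphetamine use. Two contrasts are supported: any
medication vs ETAU (medication and medication+navigation arms collapsed)
and medication+navigation vs medication alone. Contrast eligibility is
derived from the arms present per study, never hard-coded, so the
two-contrast analysis generalizes beyond three studies.

The fit is maximum likelihood by IRLS (standard GLM initialization
`mu0 = (y+1/2)/2`, step-halving if the deviance rises, relative-deviance
tolerance 1e-8, 100 iterations). Separation is flagged when a coefficient
exceeds 10 in absolute value along the IRLS path or the deviance cannot be
made to decrease; flagged or non-converged fits are re-run with Firth
(Jeffreys-prior) penalization, whose maximum is finite even under complete
separation. This matters because the resampling stages re-fit the model on
hundreds of thousands of replicates: degenerate replicates are retained
through the penalized fallback and counted, never dropped. Covariates
constant within a study (or made constant by resampling) are dropped from
that fit with a warning.

**Stage 2.** Fixed-effect inverse-variance pooling:
`w_j = 1/Var(theta_j)`, `theta_p = sum w_j theta_j / sum w_j`,
`se_p = sqrt(1/sum w_j)`. No between-study heterogeneity term at this
stage; heterogeneity is the Bayesian model's job. The pooled value always
lies in the convex hull of the study estimates and is invariant to study
order and to rescaling all weights.

## Resampling inference

**Permutation test.** The randomization null is realized by re-assigning
treatment labels uniformly at random *within each study*, preserving
treated/reference counts; each replicate re-runs the entire two-stage
estimator. P-values use the add-one rule `(count+1)/(B+1)`, so
`1/(B+1) <= p <= 1`. Both sidedness conventions are computed — one-sided
for the alternative `theta_p > 0` and two-sided on `|theta_p|` — with the
two-sided value as the headline default. (The stated one-sided alternative
runs opposite to the direction of a hypothesized treatment benefit, which
would be an odds ratio below 1; the package reports both and takes no
position.) Default B = 5,000. An exhaustive-enumeration oracle computes
the exact randomization p-value on instances with at most 50,000
assignments and anchors the Monte-Carlo test in the suite.

**Bootstrap.** Participants are resampled with replacement within
study x arm strata, keeping every design fixed; the 95% interval is the
percentile interval of replicate pooled log-ORs (default B = 2,000). The
OR-scale interval is defined as the elementwise exponential of the
log-scale endpoints, so monotone-transformation equivariance holds by
construction. Percentile rather than BCa was chosen for transparency and
because the estimand is already on a symmetric (log) scale; the interval
type sits behind the same contract and could be swapped.

## Bayesian hierarchical sensitivity model

Participant level: `y_ij ~ Bernoulli(logit^-1(alpha_j + x'beta_j +
theta_j t_ij))` with `theta_j ~ N(theta_p, tau^2)`,
`theta_p ~ N(0, 10^2)`, `tau ~ Half-Normal(1)`, nuisance coefficients
`N(0, 10^2)`. The priors are weakly informative on the log-odds scale; the
half-normal scale of 1 allows substantial but not unbounded between-study
heterogeneity. As `scale_tau -> 0` the posterior for `theta_p` contracts
onto the fixed-effect pooled estimate (tested over scales 1, 0.1, 0.01).

Sampling is adaptive random-walk Metropolis within Gibbs with three
mixing-critical choices:

* non-centered parameterization `theta_j = theta_p + tau u_j`, which keeps
  the sampler healthy when the data are weak (including prior-only runs)
  and when tau is small;
* interweaved conjugate updates: after each non-centered sweep, `theta_p`
  is redrawn from its centered full conditional given `(theta_j, tau)` and
  `tau` from its centered conditional given the `theta_j` residuals —
  both likelihood-free — which breaks the `theta_p <-> u` ridge when the
  data are informative;
* per-study joint proposals over `(theta_j, alpha_j, beta_j)` shaped by
  the Cholesky factor of the frequentist covariance, carrying the
  treatment/intercept correlation that axis-aligned updates cannot.

Scalar step sizes adapt by Robbins-Monro only during warmup (target
acceptance 0.30 for scalars, 0.25 for the multivariate blocks; adaptation
frozen afterwards so the post-warmup chain is a fixed Markov kernel).
Warmup equals the number of retained draws; no thinning. Convergence is
reported per parameter (split-Rhat and ESS via arviz); the summary carries
a prominent non-convergence flag when any Rhat > 1.05 or ESS < 100, and
the result is still returned for the caller to judge. Defaults (2 chains,
1,000 retained draws each) satisfy the thresholds on cohorts at the
default design sizes.

A summary-level normal-normal variant replaces the likelihood with fixed
study estimates `(theta_hat_j, var_j)`. It is conjugate except for tau and
serves as the closed-form limit oracle: with tau fixed at 0 and a flat
pooled prior, the `theta_p` posterior is exactly
`Normal(theta_IV, 1/sum(1/var_j))`.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the motivating collaborative:

* **Designs** — three studies of 110 (58/52), 69 (29/21/19) and 151
  (46/54/51) participants; combined N = 330 (the analyzed sample).
* **Treatment effects** — common conditional log-ORs `log(0.67)` (any
  medication vs ETAU) and `log(0.61)` (navigation vs medication alone),
  the published headline odds ratios used as generating values. The
  effects sit on the conditional (covariate-adjusted) scale so that
  parameter-recovery checks target the same estimand the adjusted
  analysis estimates; by noncollapsibility of the odds ratio the crude
  (marginal) OR in generated data is slightly attenuated relative to the
  conditional value — documented, not reconciled.
* **Covariates** — age ~ Normal(39.2, 10.9) clipped to [18, 80]; female
  0.212; race (Black/White/Other) 0.491/0.409/0.100; Hispanic 0.294;
  unhoused 0.319 — the printed baseline marginals. Prior stimulant
  (cocaine/amphetamine) use is published only as days-of-use means, not a
  binary prevalence; 0.65 was chosen once as a realistic any-use rate for
  this population. Covariate effects default to modest log-odds
  associations (age -0.015/yr, female -0.2, White +0.1, Other -0.1,
  unhoused +0.3, stimulant use +0.4).
* **Baseline intercept** — 0.55 on the log-odds scale, calibrated once at
  design time (bisection at n = 2e6) so that the control arm's
  *post-imputation* outcome prevalence is 75%, the published control-arm
  rate, under the default covariate effects and missingness.
* **Missingness** — MCAR at rate 0.15 among participants in the community
  (the source gives no rate; 15% is typical 6-month attrition in this
  population), with an outcome-dependent logit-shift mechanism available
  for sensitivity work.
* **Exclusions** — zero by default, so the default analytic N equals 330.
  `consort_flow_config()` scales enrollment to 488 with exclusion rates
  48/488 (prison transfer) and 110/488 (incarcerated at follow-up),
  emulating the published participant flow. Exclusion statuses are drawn
  independently of the outcome; a dependence knob exists only through the
  outcome-dependent missingness mechanism.

Randomness comes from one root integer seed; each study uses fixed
substreams (`[seed, study_index, stage]`), so cohorts are byte-identical
across runs and stable under study-count changes.

What the generator does *not* emulate: visit schedules, medication
adherence trajectories, time-to-event structure, site-level differences in
assessment practice, or covariate correlation (covariates are drawn
independently). Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
real-data features outside it.

## Test and simulation sizes

Operating-characteristic checks run at the design sizes (N = 330) with 300
simulated datasets and B = 200 resampling replicates: type-I error is
required to fall in [0.03, 0.08] at alpha = 0.05, bootstrap coverage in
[0.92, 0.98] at the 95% level. Bias is assessed at 10x the design sizes
over 300 replicates (within 3 Monte-Carlo SEs of the generating value).
Bayesian credible-interval calibration uses 100 replicate MCMC fits
(coverage >= 90%). These sizes give the checks enough resolution to catch
real defects while keeping the default suite quick to run.

## Known limitations

* Fixed-effect pooling has no frequentist heterogeneity diagnostic;
  between-study variation is assessed only through the Bayesian model.
* The percentile bootstrap can undercover for very small studies with
  heavy separation; the penalized fallback bounds, but does not remove,
  this effect.
* The missing-as-positive rule is a worst-case sensitivity stance, not a
  missing-data model; no multiple imputation is provided.
* The MCMC sampler is a random-walk scheme: adequate for the model's
  dimension (about 30 parameters at the default designs) but not intended
  for much larger covariate sets or many-study hierarchies.
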