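# Methods

## Model

`petbold` fits linear Gaussian latent variable models of the form

    eta_i = alpha + B x_i + zeta_i,   zeta_i ~ N(0, Psi)
    y_i   = nu + Lambda eta_i + Gamma x_i + eps_i,   eps_i ~ N(0, Theta)

so the implied moments are mu(x) = nu + Lambda (alpha + B x) + Gamma x and
Sigma = Lambda Psi Lambda' + Theta.  Two concrete models are built:

* **Common model** — one PET latent over the six log BP_ND indicators, one
  fMRI latent over the four BOLD contrast indicators, fitted to all
  subjects irrespective of group.  Age and sex feed both latents; 5-HTTLPR
  class and weight-adjusted injected tracer mass feed the PET latent only.
  Latent means are fixed to 0, indicator intercepts are free, the latent
  covariance psi_12 is free.
* **Group model** — per-group (MDD / HC) specifications estimated jointly.
  Latent means (HC fixed at 0 as reference level) and the full latent
  covariance matrix are group-specific; loadings, intercepts, residual
  (co)variances and covariate paths are shared.  Covariate effects attach
  directly to the indicators rather than the latents, and all non-reference
  loadings within a latent are constrained to a single shared parameter
  (one per latent); the unconstrained per-indicator variant is retained as
  a sensitivity analysis.  These sharing choices are the identification
  conditions under which group differences in latent means and in psi_12
  are estimable from a two-group design.

Assumptions: conditional multivariate normality of the indicators given
covariates, linearity of all paths, a common residual covariance across
groups, and complete cases (rows with any missing modelled value are
dropped and counted).  BP_ND is strictly positive and modelled on the
natural-log scale; the pipeline applies the log transform, and centres age
and injected mass at the sample mean (centring moves only intercepts, not
covariance parameters).

Reference indicators carry the fixed unit loading: first ROI of each block
(putamen for PET, amygdala for fMRI) by default, overridable in the model
builders.  The normalised latent correlation is invariant to this choice up
to reparameterisation, which the test suite verifies.

## Estimation

Full-information Gaussian maximum likelihood.  Each subject contributes
log phi(y_i; mu(x_i), Sigma) with subject-specific mean and common
covariance; multigroup fits sum per-group blocks over the union of free
parameters, with equality constraints implemented by parameter aliasing
(one underlying value), so constraints hold exactly.

* Optimiser: BFGS on the raw parameter scale with analytic gradients.
  Points where Psi or Theta fails a Cholesky factorisation receive a large
  sentinel value, so line searches retreat; no barrier reparameterisation
  is used, keeping psi_12 and the residual covariances directly
  addressable for Wald and score tests.
* Defaults: gradient tolerance 1e-6 (fits accepted below an inf-norm of
  1e-3), at most 2000 iterations, 3 multiplicative-jitter restarts seeded
  from the run seed.  Non-convergence raises an explicit error carrying
  the best point found — it is never silently substituted.
* Starting values are moment-based: column means for intercepts, half
  column variances for residual variances, reference-scaled covariances
  for loadings.
* Standard errors come from the inverse observed information (numerical
  Hessian of the negative log-likelihood via central differences of the
  analytic gradient).  Expected information and robust/sandwich errors are
  out of scope.

## Inference

* **Latent correlation**: r = psi_12 / sqrt(psi_11 psi_22), delta-method SE
  with gradient (−r/(2 psi_11), −r/(2 psi_22), 1/sqrt(psi_11 psi_22)),
  Wald CI and p.
* **Moderation**: Wald contrast of psi_12 between groups on the covariance
  scale (variance from the joint vcov, var1 + var2 − 2 cov); the
  correlation-scale difference is reported as a secondary delta-method
  output.
* **Score tests**: for a candidate path (extra residual covariance,
  cross-loading, covariate→indicator path) the statistic is U' I^{-1} U at
  the constrained MLE with the candidate appended at its null value, df = 1;
  the reported estimate/SE are the one-step Newton approximation.  The fit
  is not re-estimated.
* **Model search**: each round score-tests all remaining candidates
  (default: all 45 pairwise extra residual covariances plus all 10
  cross-loadings), adjusts that round's p-values family-wise (Holm by
  default, Bonferroni optionally), frees the single best path if its
  adjusted p < alpha = 0.05, and repeats until none survives.  The trail
  records every round.  Accepted residual covariances are carried into the
  group model (a flag disables carrying).
* **Demographics**: Mann–Whitney U with midranks (exact enumeration up to a
  combined n of 16 under the auto rule, refusing exact above 20; otherwise
  a normal approximation with continuity and tie correction) and exact
  Fisher tests computed by full hypergeometric enumeration.  The default
  two-sided Fisher rule is the point-probability convention (sum of tables
  no more probable than the observed one); a tail-doubling option is
  provided.  On the published group counts the printed sex p-value (0.004)
  is reproduced by the doubling rule while the printed genotype p-value
  (0.84) is reproduced by the point rule — the two conventions genuinely
  disagree at the printed precision on these tables, and the package
  exposes both.

## Synthetic cohorts

The generator emulates the cohort the analysis assumes: 88 MDD + 50 HC by
default, bivariate-normal latents with per-group correlation (0.20/0.20),
latent variances 0.02 (log BP_ND scale) and 0.28 (contrast scale) so the
latent covariance is about 0.015, loadings inside the ranges the fitted
models produce (PET 1.00–1.84, fMRI 0.36–1.00), a negative MDD shift on
the PET latent mean (−0.05 log units), near-zero covariate effects, sex
frequencies 62/88 and 46/50, an S′-carrier frequency of 0.72, per-group
log-normal injected-mass distributions (means 0.013/0.015 µg/kg), and an
injected caudate–putamen residual correlation of 0.3.  PET noise is added
on the log scale and exponentiated, so the fitted log-linear model is
exactly correctly specified and stored BP_ND is positive for every seed —
parameter recovery is thereby a sharp test, not an approximation.

What the generator does **not** emulate: heavy-tailed or skewed indicator
noise, site/scanner effects, missingness mechanisms, nonlinear
covariate effects, and any voxel-level structure.  Passing recovery and
calibration tests therefore certify the estimator and test implementations
under the assumed model, not robustness to violations of it.

Two config variants support the benches: `homogeneous()` (no group shift,
equal correlations — the common model is then exactly correct) and
`equal_loadings()` (all non-reference loadings equal within a latent — the
constrained group model is then exactly correct).

## Calibration benches and problem sizes

All replicate streams are spawned from a single seed; reruns are
bit-reproducible.

* **Moderation Wald type-I**: cohorts at the emulated study size
  (88 + 50), equal-loading, equal-correlation truth, constrained group
  model without covariate paths (the generator's covariate effects are
  near zero), 1000 replicates.  Measured rate ≈ 0.044 at alpha = 0.05.
* **Score-test type-I** and **search FWER**: benched at four times the
  emulated cohort (352 + 200) with the covariate-complete common model.
  The chi-square(1) reference for the score statistic is exact there
  (with iid multivariate-normal draws the measured rate is 0.050 at
  n = 552), and the 12-candidate Holm search keeps its family-wise error
  at ≈ 0.05.
* **Known limitation — small-sample liberality**: at the study's own size
  (n = 138, roughly 4–5 observations per free parameter) the score test
  rejects a true null in ≈ 0.07 of replicates and the 12-candidate search
  adds a spurious path in ≈ 0.09 — the chi-square tail underestimates the
  score statistic's finite-sample spread.  This is a property of the
  statistic, not of this implementation (the statistic matches a full
  information recomputation to four decimals and converges to the
  likelihood-ratio statistic at large n); score-based model search results
  at this scale should be read with that liberality in mind.  The
  `petbold calibrate` commands reproduce either regime.
* **Designed detection**: the injected caudate–putamen residual
  correlation (0.3) is near the Holm-corrected detection boundary at
  n = 138 (exact-recovery rate ≈ 0.2); the detection bench therefore runs
  at n = 1000 (600 + 400), where the search finds the path in every
  replicate and adds nothing else in ≈ 0.94.
* **Oracle comparisons**: score vs likelihood-ratio refit at n = 1000;
  delta-method vs 200-draw nonparametric bootstrap SE of r at n = 500;
  parameter recovery on one cohort of n = 10 000; bias of the ML latent
  correlation estimated over replicated cohorts at n = 138 (measured
  bias −0.0003 ± 0.0034 over 1000 replicates).

## Numerical choices and degenerate inputs

Ties in the search are broken by adjusted p, then raw p, then candidate
order, making trails deterministic.  Zero-variance indicator columns are
rejected as degenerate before fitting.  Two-sided Mann–Whitney p-values are
capped at 1; completely tied samples return p = 1.  Non-PD parameter points
are invalid (sentinel likelihood), and non-positive latent variance
estimates make the correlation undefined rather than silently clipped.
Wald CIs are symmetric (estimate ± 1.96 SE) and may exceed [−1, 1] near the
boundary by construction.

## Known limitations

Gaussian likelihood only (no ordinal indicators, no FIML for missing data,
no more than two latents or groups); the max-statistic joint adjustment
used by some SEM software for model search is not implemented (Holm /
Bonferroni only); expected-information and sandwich standard errors are
not provided; and the small-sample behaviour of score-based search noted
above.
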