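# Methods

This note documents the generative model, the five estimation procedures,
the numerical choices behind them, and what the synthetic design does and
does not establish.

## Synthetic cohorts

**Exposures.** 50 Bernoulli exposures with prevalences log-evenly spaced
and descending from 3% to 0.005% (`p_k = 0.03 * (5e-5/0.03)^((k-1)/49)`).
Five are relevant -- x1, x13, x26, x39, x50, i.e. log-evenly spread across
the prevalence range -- with unit log-odds effects of alternating sign
(`-x1 +x13 -x26 +x39 -x50`); the remaining 45 have effect exactly 0. The
full grid being log-even (not only the relevant points) is corroborated by
the irrelevant-group boundaries it implies (0.9%-3%, 0.25%-0.8%, ... with
exactly 9 variables each), which no other natural spacing reproduces.

**Dependence.** Pairwise association is expressed through common
probabilities `P(x_i, x_j) = P(x_i) P(x_j) 2^{h_ij}`, `h_ij` i.i.d.
normal with mean 0 and variance 0.25 (read as variance; sd 0.5), clamped
to the Frechet bounds `[max(0, p_i+p_j-1), min(p_i, p_j)]`. Sampling uses
the latent-Gaussian threshold construction: per pair, the latent
correlation solves `Phi2(qi, qj; rho) = c_ij` where `Phi2` is evaluated
through the tetrachoric integral (`Phi(a)Phi(b)` plus a 64-node
Gauss-Legendre correction term -- the additive form stays accurate when
the joint probability is ~1e-8) and the root is found by vectorized
bisection to width 1e-10. The assembled correlation matrix is repaired to
the nearest PSD matrix by eigenvalue clipping at 1e-8 with diagonal
renormalization before Cholesky sampling.

**Outcome.** `P(y=1|x,z) = logit^{-1}(b0 + sum b_j x_j + g z1 - g z2)`
with `b0 = 0` (50% baseline) and two independent unobserved Bernoulli(0.5)
confounders. Their magnitude is calibrated to a signal-to-noise ratio of
3: `g = sqrt(Var(X b) / (3 * 2 q (1-q)))` with the signal variance taken
empirically over the population. At the study design this gives
`g ~ 0.156`.

**Sampling.** Each replicate simulates a fresh population of 100,000
(fresh `h`, exposures, confounders, outcomes -- the conservative reading
of replication) and draws exactly 5,000 cases and 5,000 controls without
replacement within outcome strata. A master seed spawns one
`SeedSequence` child per replicate and per stage, so any stage of any
replicate reproduces in isolation and parallel execution equals
sequential.

**What the generator does not emulate.** Real registry data has
covariate-dependent sampling, measurement error, missingness, structured
confounding (age, sex, alcohol, ...) and non-unit effect sizes. Passing
results here demonstrate the operating characteristics of the estimators
under clean, weakly-dependent rare exposures -- not performance on any
particular epidemiological dataset.

## Estimators

All estimators see only the exposures and the outcome (never `z`), always
keep the intercept unpenalized (it absorbs the case-control sampling
fractions), and treat an all-zero exposure column as unestimable: flagged
nonconvergent (hence not selected) for ML and Firth, coefficient 0 for
the penalized methods.

**ML + backward elimination.** IRLS (damped Newton with step-halving, up
to 50 iterations, gradient tolerance 1e-8). From the full model, any
coefficient with |b| > 10 -- an odds ratio beyond e^10, the operational
symptom of monotone likelihood -- is dropped and marked not selected;
otherwise the highest Wald p-value is eliminated (ties: lowest index)
until all remaining p < 0.157, the AIC-equivalent threshold. Wald
p-values are used for ranking; the threshold corresponds to a
likelihood-ratio statistic of 2 only approximately under Wald, which is
the main open reading of the procedure and is recorded here as the
implemented choice.

**Firth.** Penalized likelihood `l + 0.5 log det I(beta)` maximized by
Firth-modified scoring with step-halving. Convergence is declared on a
vanishing Newton step, or on a penalized-likelihood plateau (< 1e-8 gain)
with small adjusted score -- the objective is extremely flat along
directions of near-zero information and pure step criteria stall there.
Elimination p-values are profile-penalized-likelihood-ratio tests
recomputed against the current working model each round: the tested
coefficient is fixed at 0 while the penalty keeps the working design's
full information matrix, and `2 * delta pll` is referred to chi-square(1).
The fitter was verified against direct quasi-Newton maximization of the
explicit penalized likelihood.

**Lasso.** Cyclic coordinate descent on the IRLS quadratic approximation
(working weights floored at 1e-5), over 100 log-spaced penalties from
`lambda_max` (all slopes zero) down to `1e-4 lambda_max`, warm-started,
with active-set iteration and a closing full sweep. Penalty factors
default to column standard deviations -- identical to standardizing the
covariates before fitting, the default of standard lasso software, and
the reason the lasso keeps selecting ultra-rare columns: a column with
two exposed subjects has sd ~ 0.014, so its raw-scale threshold is ~70x
lower than a common column's. One 10-fold CV pass (folds fixed up front,
a pure function of the seed) picks `lambda_min` by total held-out
binomial deviance. The kernel is numba-compiled over a
compressed-sparse-column view; sweeps cost O(nnz), not O(np).

**Ridge.** Penalized IRLS with the same sd-scaled penalty, tuned by
10-fold CV over 100 log-spaced penalties in [1e-4, 1e4] (warm-started
heavy-to-light). Selection: 100 bootstrap resamples are refit at the
tuned penalty (re-tuning inside each resample is not performed -- tuning
is described as a one-off, and re-tuning would multiply the cost 100-fold
with no stated mandate); a variable is selected iff the [0.025, 0.975]
empirical quantile interval of its bootstrap coefficients excludes 0.
Fold-level fits run through a sparse-information Newton solver that
matches the dense IRLS to the same tolerance.

**Boosting.** Component-wise likelihood boosting: from the intercept-only
fit, each step fits every candidate one-variable offset model
`g_j0 + g_j x_j` by a single penalized Fisher-scoring step from zero
(slope penalty `lam * g_j^2`; the candidate's own intercept is refit,
matching the stated recursion), selects the candidate maximizing the
exact penalized offset log-likelihood at its step estimate (ties: lowest
index), and accumulates; a variable's coefficient is the sum of its step
updates. The candidate criterion is evaluated as a 4th-order Taylor
expansion in the (tiny) intercept adjustment plus an exact sparse
correction over exposed rows; the expansion was checked to reproduce the
exact dense evaluation's selections. Stopping: `df(m)` is the trace of
the cumulative boosting hat operator via the rank-2 recursion
`Q_m = Q_{m-1} + M_m (I - Q_{m-1})` (the corrected variant of the df
construction; stores kept in float32), `AIC(m) = -2 l(m) + 2 df(m)`, and
`M_optimal = argmin AIC` over 500 steps. The penalty only needs to be
coarse: the default `lam = 200` puts `M_optimal` of the study design
comfortably inside (50, 500); whenever `M_optimal < 50` the penalty is
doubled and the run restarted (up to 5 times) -- doubling, because a
larger penalty means smaller steps and hence a later optimum.

## Evaluation

Selection rates are percentages over (replicate, variable) pairs:
true-positive rates for relevant variables, false-positive rates for
irrelevant ones, the latter pooled into five prevalence groups of 9
variables (sort irrelevant prevalences descending, cut into consecutive
nines; rarest group reported first). Bias is `bhat - b` and MSE the mean
squared deviation across replicates, with unselected variables
contributing an estimate of exactly 0 -- the only convention under which
a never-selected relevant variable shows a mean bias of exactly +/-1.
Summaries carry binomial Monte-Carlo standard errors
(`sqrt(r(1-r)/pairs)`) so that tolerance statements are principled.

## Problem sizes

The package's own test suite fits all five methods on 20 study-scale
replicates (a shared session fixture); `scripts/acceptance.py` uses 100
replicates for ML and the lasso, 30 for boosting and 20 for Firth and
ridge. These counts were chosen as the smallest at which the published
rates are distinguishable from their complements given binomial
Monte-Carlo error; single-variable rates at 20 replicates carry standard
errors up to ~11 percentage points.

## Known limitations

* Selection rates for the rarest exposures are bounded by carrier
  availability: at prevalence 0.005% a fresh 100,000-subject population
  carries Poisson(5) exposed subjects, of whom ~10% land in the sample,
  so only ~36% of replicates contain any exposure at all. Ultra-rare
  selection rates therefore depend strongly on whether populations are
  resimulated per replicate (done here) or one realized population is
  resampled; our lasso decisions were verified identical to R's
  `cv.glmnet` replicate-by-replicate, so the residual gap to published
  ultra-rare lasso rates is attributable to that generative reading, not
  to the fitter.
* CV-tuned ridge shrinks even the most common (3%) unit effect to around
  -0.65 in this design; this matches R's `cv.glmnet` on identical data
  and is a property of deviance-optimal L2 tuning with 45 noise columns,
  not of this implementation. Read ridge's absolute coefficients
  accordingly.
* A faithful Firth + profile-penalized-likelihood backward elimination
  selects a 0.02%-prevalence unit effect in roughly a fifth of
  replicates (whenever the 2-3 exposed subjects are all cases, the PLR
  statistic is ~4); it does not reproduce a 0% selection rate at that
  prevalence under this generative design.
* The Wald-vs-LRT reading of ML backward elimination changes rates for
  sub-0.1% exposures (LRT fires on separated columns; Wald does not).
  Wald is implemented.
* Boosting df uses one specific (corrected, cumulative-trace) variant of
  the hat-operator construction; other variants shift `M_optimal` and
  with it the common-variable false-positive rates.
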