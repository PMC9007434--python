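# Methods

## Structural model and estimand

All estimators operate on per-variant summary statistics under the linear
structural model

    X_i  = G_i' β_X + γ_X U_i + ε_Xi
    W_ij = G_i' β_Wj + γ_Wj U_i + ε_Wij ,   j = 1…k
    Y_i  = θ X_i + W_i' δ + γ_Y U_i + ε_Yi ,

with independent variants G_ij ~ Binomial(2, π), a shared unmeasured
confounder U, and independent unit-variance noise. The reduced form is
Y_i = G_i'β_Y + …, with β_Y = θβ_X + β_W δ, which is why per-variant
regression slopes of Y on G recover θβ_X + β_W δ and why IVW is biased by
exactly (β_X'Σ_G β_W δ)/(β_X'Σ_G β_X) when δ ≠ 0. The estimand θ is the
direct effect of the risk factor, holding the measured covariates fixed;
identification requires p ≥ k + 1 and full column rank of [β_X β_W], which
the data containers enforce.

Covariate j opens a pleiotropic path only when δ_j ≠ 0 *and* β_Wj ≠ 0. The
generator therefore supports two sparsity regimes: `delta_sparse` (most
δ_j = 0; every covariate is genetically predicted) and `betaW_sparse` (all
δ_j ≠ 0; most β_W columns are zero). Which covariates are pleiotropic is
randomized per replicate to avoid position artifacts.

## Estimators

* **IVW** — weighted regression of β̂_Y on β̂_X through the origin, weights
  se(β̂_Y)⁻².
* **Multivariable IVW** — the same regression with covariate association
  columns added; used with all covariates (`MV-All`), a user-specified
  subset, the truly pleiotropic set in simulations (`Oracle`), or a
  data-selected set.
* **Regularized (Reg)** — the partially penalized fit, solved by the exact
  two-step reduction: (1) a standard Lasso of P S^{1/2}β̂_Y on
  P S^{1/2}β̂_W, where P annihilates S^{1/2}β̂_X; (2) closed-form recovery
  θ̂ = (β̂_Y − β̂_W δ̂)' S β̂_X / (β̂_X' S β̂_X). The equivalence of the
  two-step solution with the joint objective is verified in the test suite
  against an independent convex solver (an L-BFGS-B solve of the
  positive-part-split quadratic program).
* **Post-regularization (Post-reg)** — unpenalized multivariable IVW on the
  Lasso support, removing shrinkage bias at some efficiency cost.

### Standard errors

All standard errors use the multiplicative random-effects convention of
established summary-data MR software: the weighted-least-squares covariance
is scaled by max(1, RSS_w/(p − q)), where q is the number of fitted
coefficients. Over-dispersion (residual heterogeneity) widens intervals;
apparent under-dispersion never narrows them. For the shrinkage estimator
`Reg` the reported SE is the IVW-model SE applied to the pleiotropy-corrected
outcome associations with q = 1 + |support|; it ignores both shrinkage and
selection uncertainty and is reported for orientation only — calibrated
inference should use the three-sample design.

## Penalty convention and tuning

The Lasso step minimizes (1/(2m))·RSS + λ‖δ̃‖₁ with m = p working
observations and working-design columns standardized to unit SD (δ̃ is the
standardized coefficient vector; estimates are transformed back). This is
the glmnet convention; λ values are not transferable to solvers with a
different scaling. The λ grid has 100 log-spaced values from λ_max (the
smallest fully sparsifying penalty, computed from the working inner
products) down to λ_max·10⁻⁴.

K-fold cross-validation folds over *variants* (the observations of the
weighted regression). For each fold and λ, the two-step fit on the training
variants predicts held-out outcome associations as θ̂β̂_X + β̂_W δ̂, scored
by se⁻²-weighted mean squared error. Training folds relax the p ≥ k + 1
check — the Lasso step does not need it. Two selection rules are exposed:
`lambda_min` (minimizer of the pooled error curve; ties resolve to the
largest λ) and `lambda_mean_min` (arithmetic mean over repeated random
partitions of the per-repeat minimizers — the stabler choice for a single
real dataset, typically with 100 repeats). Simulation studies use a single
CV with `lambda_min` per replicate. Note that with p = 10 and K = 10 the CV
is leave-one-out, where every partition yields the same folds and repeating
adds nothing; LOO-CV occasionally selects the unpenalized end of the grid,
which makes the shrinkage estimator heavier-tailed across replicates than
its central spread suggests (its mean is unaffected; see Limitations).

## Selection-aware inference

Refitting on a data-selected covariate set and reading off the usual SE
ignores the selection event, so two-sample post-regularization intervals
undercover. Two remedies are provided:

* **Three-sample design** — an independent summary dataset is used only to
  select covariates (regularized fit with CV λ); multivariable IVW with that
  set is then fitted on the analysis data. In the simulator the third sample
  is an independent one-sample summary; the analysis data remain two-sample.
* **Double estimation** — two fully penalized, intercept-free Lassos select
  covariates predicting β̂_X (unweighted) and β̂_Y (rows scaled by se⁻¹,
  folding in the outcome error model), each with its own CV λ; the final
  multivariable fit uses the union support. The exposure-side design is
  unweighted because no exposure error model is imposed.

Intervals are normal-theory: θ̂ ± z·SE.

## Balancing diagnostic

For a candidate covariate set, the outcome associations are residualized on
the included covariate associations by ordinary least squares with an
intercept, and the residuals are correlated with β̂_X and every β̂_W column.
Under unweighted OLS the within-set correlations are exactly zero, making
the table easy to read: remaining non-zero covariate correlations flag
unaccounted pleiotropy, and the β̂_X correlation shows how much instrument
signal survives adjustment. A weighted variant (rows scaled by se⁻¹) is
available behind a flag; the unweighted form is the default and the
convention used in the tests.

## Synthetic data and study conditions

The scenario presets fix the study conditions used throughout the tests:
n = 20 000 individuals per sample, π = 0.3, γ_X = γ_Y = 1, γ_Wj = 1/k;
Scenario 1 has p = 10, k = 8, β_X ~ U(0.15, 0.3), β_W ~ U(−0.2, 0.4);
Scenario 2 has p = 80, k = 70, β_X ~ U(0.05, 0.12), β_W ~ U(−0.1, 0.15);
nonzero δ ~ U(−0.2, 0.3); θ ∈ {0, 0.2}; pleiotropic counts 1/2/4
(Scenario 1) or 7/21/35 (Scenario 2). These ranges imply instruments
explaining about 9.9% (Scenario 1) and 11.5% (Scenario 2) of exposure
variance by the definition Var(G'β_X)/Var(X); other R² conventions (e.g.
the fitted multiple-regression R² in a finite sample) give figures a few
tenths of a percentage point different. Summary statistics are produced the way GWAS consortia produce
them: a simple linear regression with intercept of the trait on each variant
in turn, exposure/covariate associations from one sample and outcome
associations (with SEs, n − 2 degrees of freedom) from an independent one.
Genotypes are drawn as the sum of two Bernoulli(π) indicators — identical in
distribution to Binomial(2, π) and much faster at scale. One generator
stream per replicate, with replicate seeds spawned from (study seed,
replicate index), makes studies reproducible and order-independent.

What the generator does **not** emulate: linkage disequilibrium between
variants, winner's-curse selection of instruments, sample overlap between
the summary datasets, binary outcomes/logistic associations, non-linear or
interaction effects, and causal structure among the covariates themselves.
Passing tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to these real-data complications.

## Numerical choices

* Lasso solves use cythonized coordinate descent. Single-λ fits target a
  duality gap of 1e-9 relative to ‖ỹ‖²; if coordinate descent stalls (it
  can on nearly square, ill-conditioned projected designs at the dense end
  of the grid) the solution is polished by a bound-constrained quasi-Newton
  solve of the split quadratic program and the better of the two solutions
  is kept. CV path fits use a 1e-5 target with a capped sweep budget — the
  error curve does not need last-digit coefficients, and λ selections were
  verified unchanged under much tighter settings.
* λ = 0 requests are solved as unpenalized (minimum-norm) least squares on
  the working data rather than through coordinate descent.
* Working-design columns with zero variance after projection are excluded
  from standardization and pinned at coefficient zero.
* Rank checks use a relative tolerance of 1e-10 on column-normalized
  designs; rank-deficient multivariable designs raise a collinearity error
  rather than silently dropping columns.
* Weighted least squares goes through statsmodels WLS; the dispersion floor
  is applied on top of its covariance.
* CV ties in the error curve resolve to the largest λ (the sparser model).
* In simulation studies, replicate-level numerical failures are logged and
  excluded; more than 1% of failures aborts the study.

## Benchmarks and their problem sizes

`scripts/acceptance.py` re-runs the benchmark studies at 1000 replicates
for the Scenario 1 means of the CV-based estimators and 300 replicates for
Scenario 2 — sizes chosen to keep the full recomputation near ten minutes on
a single CPU while holding the Monte-Carlo error of the reported means near
±0.003 and ±0.006 respectively. The two heavy-tailed Scenario 1 statistics
are computed from larger batches (6000 replicates for the closed-form SD
benchmarks, 3000 for the post-regularization null mean), because their
1000-replicate sample statistics carry Monte-Carlo error comparable to the
effects being measured (see Limitations).
The test suite asserts each benchmarked statistic within three Monte-Carlo
standard errors of its reference value (computed from the replicate spread,
with a moment-based SE for SD statistics) plus the print-rounding of the
3-decimal reference values.

## Limitations

* The full multivariable fit in Scenario 1 (10 variants, 9 coefficients)
  has one residual degree of freedom; its estimate distribution is extremely
  heavy-tailed, and any sample SD of it — including the benchmark value —
  carries Monte-Carlo error of order ±0.05–0.09 even at 1000 replicates.
* The shrinkage estimator's replicate SD depends strongly on how often CV
  selects the unpenalized end of the grid (see Tuning); with LOO-CV at
  p = 10 this happens in roughly a sixth of replicates, so its tails are
  heavier than the oracle's even though its central behavior matches.
* `Reg` standard errors ignore selection/shrinkage uncertainty by
  construction; use the three-sample design for calibrated intervals.
* k ≥ p is rejected, not supported; no correlated-variant (LD) support; no
  intercept term for unmeasured directional pleiotropy.
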