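# Methods

## Model and estimation

All models are held in RAM form: a directed matrix `A` (acyclic; factor
loadings, covariate regressions, structural paths), a symmetric matrix `S`
(residual and exogenous (co)variances) and a mean vector `M`.  With
`T = (I − A)⁻¹`, the implied moments of the observed block are
`Σ = F T S T′ F′` and `μ = F T M`.  Growth-factor loadings are fixed by
design — intercept `(1,…,1)`, slope `(0,1,…,6)`, optional quadratic
`(0,1,4,…,36)` — encoding one unit of latent slope per annual wave.

The likelihood is multivariate normal.  Two estimators share one code
path built on per-missingness-pattern sufficient statistics
`(n_g, ȳ_g, C_g)`:

* **ML** uses listwise-complete rows (a single pattern);
* **FIML** evaluates each pattern's observed subvector against the
  matching submatrix of `(Σ, μ)`, which is valid when missingness depends
  only on observed data (MAR).

The gradient is analytic: the per-pattern normal-theory derivatives are
accumulated into `G = ∂ℓ/∂Σ` and `g_μ = ∂ℓ/∂μ`, then chained through the
RAM identities `∂(TST′)/∂A_ij = T[:,i] V[j,:] + V[:,j] T[:,i]′` (with
`V = TST′`), `∂Σ/∂S_ij = W[:,i] W[:,j]′ + (transpose)` and
`∂μ/∂M_i = W[:,i]`, `W` being the observed rows of `T`.  The score is
verified against central finite differences in the unit suite.

Variances are optimized on the log scale; covariances are unconstrained
cells with positive definiteness of `Σ` enforced by an evaluation-time
barrier.  Optimization is L-BFGS-B on the per-observation negative
loglik, followed, when the gradient max-norm is still above tolerance, by
Levenberg-damped Newton steps whose Hessian comes from central differences
of the analytic gradient.  The convergence flag requires a gradient
max-norm below 1e-4 on the per-observation working scale; this is looser
than the 1e-5 one might use with exact Hessians because the final Hessian
is itself finite-differenced, and 1e-4 on the per-observation scale
already corresponds to a change far below any reported digit.
Non-convergence is reported in the result object, never raised.

Start values are deterministic: per-subject OLS trajectory fits give the
factor means, their covariance gives the `Ψ` block, pooled residuals give
`θ_t`; regressions start at zero.

**Covariates.** Exogenous observed covariates are profiled: the joint
likelihood factorizes as `p(x) p(y|x)`, so their means and covariances are
fixed at the sample values during optimization while still counting as
free parameters in the degrees of freedom
(`df = p(p+3)/2 − free parameters`, covariate moments included).  Under
FIML, rows missing a covariate are dropped with a logged count — the
covariates are treated as fixed regressors, not modeled outcomes.

**Standard errors** are the square roots of the inverse numerical Hessian
(central differences of the analytic gradient, relative step 1e-4) at the
optimum, mapped through `exp` for log-scale variances by the delta method.

## Fit evaluation

χ² is the likelihood-ratio statistic against the saturated model,
`2(ℓ_sat − ℓ_model)`, so ML and FIML share one definition; with complete
data it equals `n·F_ML` (the classical `(n−1)·F_ML` differs only by the
`n/(n−1)` factor).  The saturated model under FIML is fitted by EM for
the unstructured multivariate normal.  The baseline (independence) model
frees means and variances with zero covariances; its likelihood
factorizes per variable, so its MLE under FIML is the per-variable
observed-case mean and variance.  CFI and TLI follow the standard
incremental formulas; TLI is reported missing when the baseline χ²/df
equals 1.  RMSEA uses `sqrt(max(χ²−df,0)/(df(n−1)))` with the 90% CI from
inverting the noncentral-χ² cdf at 0.95/0.05; the plain-`n` denominator
is available by flag because SEM programs differ on this convention and
the printed values of the motivating study cannot adjudicate it.
Adequacy is the conjunction CFI ≥ .90, TLI ≥ .90, RMSEA ≤ .08.

The linear-vs-quadratic comparison is a likelihood-ratio test on nested
fits (same data, by hash), and the quadratic model is preferred only when
the LR test rejects at 0.05 *and* the quadratic mean and variance are
jointly significant by a Wald test — a parsimony rule that avoids keeping
a factor whose own parameters are indistinguishable from zero.

## The parallel-process model

Three linear growth structures (BMI, PCS_PA, PCS_HDB) share one model.
The BMI intercept is regressed on the two behavior intercepts (a paths);
the BMI slope on the behavior intercepts (b paths) and slopes (c paths).
The four predictor factors covary freely; BMI disturbances covary with
each other but not with the predictors, matching the regression
direction.  Covariates predict all six growth factors by default (a
`covariates_predict="bmi"` flag restricts them to the BMI factors, since
the original specification is ambiguous on this point).  "Time-varying
confounding by the respective behaviors" is absorbed as free within-wave
residual covariances among the three processes
(`wave_residual_policy="free"`); wave-specific regressions
(PA_t → BMI_t) are a deliberate non-goal — residual covariances are the
standard parallel-LGCM device and keep the growth-factor paths
interpretable.

## Composites

Each behavior battery (three Likert items) is reduced per wave by PCA of
the item **correlation** matrix on that wave's complete cases —
correlation, not covariance, because the items use different Likert
ranges (8/6/4 points for PA; 5 points each for HDB).  The first component
is retained under the eigenvalue > 1 rule (a warning fires if the rule
would retain a different count).  Loadings are sign-oriented so their sum
is positive (tie broken by the first item), preventing wave-to-wave sign
flips, so higher scores always mean more of the behavior.  Scores are the
first-component projection of standardized items, z-scored within wave by
default ("pooled" scope available; the original study's choice between
the two is not recoverable from its report).  A missing item yields a
missing score — items are never imputed; FIML handles the gap downstream.

## Synthetic cohort

The generator emulates the study conditions the estimators assume, one
stratum at a time (six strata: gender × baseline weight status at the
published sizes 223/530/319 male and 663/405/439 female):

* **Growth truths.** Published stratum estimates supply the marginal
  factor means and the intercept-slope covariances of all three
  processes, and the six structural paths.  The BMI factors are built
  structurally — intercept from the a paths, slope from the b and c
  paths, plus disturbances — with structural intercepts derived so the
  *marginal* BMI means hit the published values.  Scales the reference
  tables do not print use documented defaults chosen to keep the implied
  covariance well conditioned: BMI disturbance SDs 3.0 (intercept) and
  0.3 (slope) with residual SD 1.0; PA/HDB disturbance SDs 0.85 and 0.12
  with residual SD 0.55.  The published covariances are interpreted as
  disturbance covariances: treating the published SD-scale values as
  marginal-variance targets would force negative disturbance variances in
  the high-path strata, so the disturbance-scale reading is the
  self-consistent one.  Cross-process residual covariances within a wave
  default to zero (the reference report does not print them; the
  parameter is exposed).
* **Covariates** are drawn independently per stratum from the published
  marginals (age and alcohol normal with clipping, categorical variables
  from the printed frequencies).  Generator-side covariate effects are
  deviation-coded so they leave the marginal factor means at their
  published targets.
* **Likert measurement.** Each item is a thresholded latent variable,
  `loading·score + unique noise`, standardized and cut at
  equal-probability normal thresholds for its category count.  The unique
  noise shares (PA 0.38, HDB 0.62) were calibrated once so that the first
  principal component of the *discretized* items carries ~71% (PA) and
  ~56% (HDB) of the item variance at large n, inside the published
  per-wave bands; discretization attenuates correlations, which is why
  the shares differ from the naive continuous-scale values.  The
  continuous process scores are also emitted (`pa_score`, `hdb_score`),
  and recovery experiments fit on them because the structural paths are
  defined on that scale; fitting on re-scored Likert items attenuates the
  paths, which the recovery harness can demonstrate but does not hide.
* **Missingness** is wave-level MAR: a monotone dropout hazard plus
  independent intermittency, both logistic in baseline age and smoking
  (defaults 0.04 and 0.05 per wave, logit shifts 0.3 per age decade and
  for smokers); wave 0, the entry screening, is always observed.  A
  missing wave blanks all seven analysis variables at that wave.

What the generator does **not** emulate: intervention effects of the
wellness program itself, real attrition dynamics, item-level (as opposed
to wave-level) nonresponse, non-normal trajectory residuals, and
measurement non-invariance over time.  Passing recovery tests therefore
show that the estimators are correct for data satisfying the model's
assumptions, not that the published substantive estimates are right.

## Validation harness and problem sizes

`recovery_experiment` simulates replicate cohorts from a known parameter
set, refits the parallel model, and reports bias, empirical SE and 95%
CI coverage per path, failing if more than 20% of replicates do not
converge.  The acceptance script uses one n = 50,000 cohort for the
headline path recovery (Monte-Carlo SD ≈ 0.026 for the normal-female
parallel PA path); the test suite uses n = 20,000 against the published
3-SE band, 500 replicates of n = 500 for χ² calibration, 50 panels of
n = 300 for the FIML/ML identity, and n = 50,000 for the Likert variance
bands.  The pipeline refuses the parallel model in strata below 100
subjects (configurable): a 27-variable covariance structure is not
usefully estimable below that, as its 405 sample moments exceed the rows
available.

## Known limitations

* No robust (sandwich/MLR) or bootstrap standard errors; plain ML/FIML
  only, which is also why the fit statistics may differ slightly from
  software using scaled corrections.
* Likert indicators are scored by PCA and then modeled as continuous;
  no categorical-indicator (WLSMV-style) estimation.
* The saturated-model EM under heavy missingness dominates FIML χ²
  run time for large p; fit indices can be skipped by evaluating only
  the parameter table.
* Degrees of freedom follow the package's own counting rule
  (`p(p+3)/2 − free`, covariate moments included).  The motivating
  study's printed dfs (73 and 362) are not reproducible from any
  standard convention we tried; its fit-index *values* are still used to
  validate the RMSEA formula and the adequacy rule, which do not depend
  on that choice.
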