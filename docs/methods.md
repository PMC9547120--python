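# Methods

## The model family

A latent change score model (LCSM) describes repeated measures
`x[1..T]` of one construct per individual through a classical-test-theory
decomposition and a structural recursion on the latent level:

    x[t]  = lx[t] + u[t]                       (observed = true + unique)
    lx[t] = lx[t-1] + dx[t],       t = 2..T    (change-score definition)
    dx[t] = Σ_f λ_f[t]·f  +  β·lx[t-1]  +  ϕ·dx[t-1]

The change scores `dx[t]` are latent differences of adjacent true scores;
they carry no residual variance of their own.  Their drivers are chosen
declaratively:

* **Constant change factor** (`alpha_constant`): one latent factor `g2` with
  unit loadings on every change score, mean `alpha_g2`, variance
  `sigma2_g2` and covariance `sigma_g2lx1` with the initial true score.
  Any per-individual constant-change effect is absorbed into this factor;
  the individual score itself is never a free parameter.  Alone it produces
  linear mean trajectories.
* **Linear change factor** (`alpha_linear`): same factor with fixed loadings
  `t − 1` on `dx[t]` (1, 2, …, T−1), giving quadratic observed
  trajectories.  The loading origin (offset 0 at the first change score) is
  a design choice of this package.
* **Piecewise constant change** (`alpha_piecewise` with change point `k`):
  `g2` loads on `dx[2..k]`, a second factor `g3` on `dx[k+1..T]`; the two
  supports partition the change scores, and `sigma_g2g3` links the phases.
* **Proportional change** (`beta`): `dx[t]` on `lx[t-1]`, equal over t.
* **Change-score autoregression** (`phi`): `dx[t]` on `dx[t-1]`, t = 3..T.

A bivariate model pairs two such constructs (`x` with factors `g2/g3`, `y`
with `j2/j3`) and adds coupling regressions: `delta_*` couplings use the
other construct's *true* scores as sources, `xi_*` couplings its *change*
scores, either concurrently (`con`, from t = 2) or lagged by one occasion
(`lag`; lagged change-score sources start at t = 3 because the source
change score must exist).  `coupling_piecewise` splits every active
coupling label into pre/post-change-point labels (suffixes `1`/`2`); its
change point is independent of the univariate one, since the two options
are declared separately.  The cross-construct covariance catalogue
comprises the paired unique-score covariance `sigma_su` (equal over t), the
initial-true-score covariance `sigma_ly1lx1`, and factor–intercept /
factor–factor covariances for whichever change factors exist.

All time-varying coefficients are constrained equal over time (one label,
several matrix cells), which is what keeps the parameter table independent
of T.  Unique variances are likewise one parameter per construct, and
unique scores are mutually uncorrelated except for `sigma_su` at equal t.

## RAM representation and implied moments

`compile_spec` lowers a specification to RAM matrices over observed
variables, true scores, change scores and change factors: directed paths
`A` (fixed unit entries for measurement, true-score autoregressions,
change-score definitions; labelled entries for regressions), symmetric
covariances `S`, means `m`.  Implied moments follow

    mu    = F (I − A)^{-1} m
    Sigma = F (I − A)^{-1} S (I − A)^{-T} F^T

with `F` the observed-variable filter.  `(I − A)` is invertible for every
valid layout; a singularity (conceivable only with pathological concurrent
coupling loops) raises a structural-cycle error rather than propagating
NaNs.

## Estimation

The likelihood is full-information maximum likelihood: each row contributes
the multivariate-normal log-density of its observed subset, so incomplete
rows are retained (valid under MCAR/MAR).  Rows are grouped by missingness
pattern; the grouped sum is numerically identical to case-wise evaluation
(tested against a case-by-case oracle at 1e-10).  Rows with no observed
values contribute nothing and are excluded from `n_used`.  A
`listwise_ml` estimator that drops incomplete rows first is available for
comparison.

Parameters are optimised on the natural scale (no log-transform of
variances) by L-BFGS-B with finite-difference gradients; a non-positive-
definite implied covariance returns a large penalty so the line search
backs away.  Start values come from the data: first-occasion mean for the
initial true-score mean, half the first-occasion variance for the initial
true-score and unique variances, the mean successive difference for
change-factor means (half its variance for factor variances), zero for
regressions and covariances.  After the first run the optimiser is
restarted once from its solution to clear the quasi-Newton memory.
Convergence is declared on the optimiser's relative-decrease criterion
(1e-11) with at most 500 iterations per run; an absolute gradient-norm
criterion is not used because finite-difference gradients at log-likelihood
magnitudes of order 10^3 carry noise of order 1e-5.  Re-fitting from a
previous solution terminates within a couple of iterations at the same
log-likelihood.

Standard errors are square roots of the diagonal of the inverse
central-difference Hessian of the negative log-likelihood at the optimum
(observed information; steps 1e-4·(|θ|+0.01)); they are reported only when
that matrix is positive definite.  p-values are two-sided Wald z.

## Fit statistics

With `p` observed variables there are `p(p+3)/2` first- and second-order
moments; `df = moments − npar`.  The likelihood-ratio χ² is
`2(ll_saturated − ll_model)`, clipped at zero.  The saturated model
(unstructured mean and covariance) has no closed form under missingness and
is estimated by EM for the multivariate normal, iterated to a relative
log-likelihood change of 1e-10 (complete data short-circuits to the sample
moments).  The independence baseline (free means and variances, zero
covariances) factorises over columns and is solved in closed form.  Then

    aic   = −2·ll + 2·npar
    bic   = −2·ll + npar·ln(n_used)
    cfi   = 1 − max(χ²−df, 0) / max(χ²_b−df_b, χ²−df, 0)
    rmsea = sqrt(max(χ²−df, 0) / (df·n_used))

SRMR is the root mean square of residuals between saturated and fitted
moments — covariance entries standardised by the saturated standard
deviations (lower triangle including the diagonal) together with
standardised mean residuals.  Published SRMR variants differ in whether
mean residuals enter; this package includes them.  The plain ML χ² is used
throughout (no mean-adjustment correction).  If the saturated or baseline
fit fails, χ²-based indices are flagged unavailable while aic/bic are still
returned.

## Simulator

Data are generated structurally: exogenous components (initial true
scores, change factors, uniques) are drawn from `N(0, S)` via a
PSD-tolerant factorisation, means added, and the recursion applied as
`v = (I − A)^{-1}(m + e)` — exactly the model's own generating equations,
so the observed vectors follow the implied multivariate normal by
construction (verified by moment matching against 10^6 draws) while the
latent scores remain available (`return_latents=True`).  Generating values
may be specified partially; omitted labels default to zero and unknown
labels are rejected.  Missingness is injected cell-wise MCAR per construct
(whole rows are never deliberately removed; cell-wise masking is what a
full-information estimator is built for).  Only MCAR is provided, and
residuals are always Gaussian — simulation results therefore say nothing
about robustness to MAR/MNAR mechanisms or non-normality in real data.

## Recovery study design (what the tests do and do not show)

The round-trip tests simulate and refit every univariate option and every
coupling option (20 replicates of n = 5000, T = 5; medians within 5% for
means/regressions, 10% for variances/covariances).  Two structural facts
shape the designs:

* A `phi`-only model is degenerate — without any change factor the change
  scores have no stochastic input, so `phi` multiplies an exact zero and is
  unidentified.  The `phi` case therefore includes the constant change
  factor.
* With a constant change factor alone, each individual's change scores are
  all equal to that factor, so change-to-change (`xi`) couplings need
  time-varying source change scores to be identified; the `xi` designs give
  the source construct an autoregression (`phi = 0.4`).  `delta` couplings
  interact with the target's change-factor mean through `δ·E[l_source]`;
  the designs use pronounced mean change so the two are distinguishable.
  Conditioning of every design was checked beforehand against the expected
  information matrix at the truth (median-of-20 Monte-Carlo noise at most
  half of each tolerance band).

These checks demonstrate internal consistency of simulator and estimator
under the model's own assumptions — not performance on real data.

## Worked-example scale

The packaged example (also the basis of `scripts/acceptance.py`) emulates a
five-session intervention: n = 500, process variable X starting near 29 and
declining, outcome Y starting near 15, lagged change-to-change coupling
`xi_lag_yx = 0.5`, 15%/10% MCAR missingness.  At this size a univariate fit
with standard errors and fit statistics takes a few seconds on one CPU; the
full recovery suite runs in minutes.  Problem sizes in the test-suite
oracles (10^6-draw moment matching, 20×10 brute-force likelihood grids)
were chosen so each check resolves the tolerance it asserts.

## Known limitations

* No robust/weighted estimators, bootstrap SEs, multi-group or ordinal
  extensions; no likelihood-ratio table beyond the reported ll/npar.
* Variances are unconstrained (Heywood solutions are possible and visible
  rather than masked); the PD penalty only guards the implied covariance.
* The syntax renderer emits this package's deterministic lavaan dialect; it
  does not parse arbitrary externally written SEM syntax.
* Standard errors rely on numerical differentiation; for nearly
  unidentified specifications (see above) the information matrix may be
  ill-conditioned and SEs are then withheld.
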