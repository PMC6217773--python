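# Methods

## The problem

Whether smoking affects body weight is hard to answer from survey data
because smoking is plausibly endogenous to weight: people may take up or
keep smoking *because* of weight concerns, and unobservables (stress,
risk attitudes, dieting behaviour) drive both. A regression of BMI on a
smoking dummy then mixes the causal effect with selection. `ordtreat`
implements the standard econometric answer for an **ordinal** outcome: a
joint model of a binary treatment and an ordered outcome with correlated
latent errors, identified by exclusion restrictions, together with the
naive comparator, a likelihood-ratio test of whether endogeneity is
present at all, and marginal treatment effects on the outcome-category
probabilities.

## Model

Latent treatment and outcome indices

    T* = γ₀ + z'γ + v,        T = 1[T* > 0]
    Y* = x'β + δT + ε,        Y = j  iff  μ_{j-1} < Y* ≤ μ_j,  j = 1..K

with (v, ε) bivariate standard normal, corr(v, ε) = ρ. The treatment
regressors z strictly extend the outcome regressors x; the excluded
variables (here: two education dummies and continuous state-level
smoking prevalence) shift smoking but are assumed to have no direct
effect on BMI. Identification fixes both error variances at 1; the
outcome equation carries no intercept (the K−1 strictly increasing
cutpoints μ absorb location), while the treatment equation has one.

δ is the treatment effect on the latent outcome scale, ρ the
endogeneity parameter. ρ < 0 with δ > 0 produces the characteristic
pattern in which the naive ordered probit (ρ forced to 0) understates or
even sign-flips the treatment effect.

### Likelihood

With c = γ₀ + z'γ and a_j = μ_j − x'β − δt, each observation's
probability is a bivariate-normal rectangle:

    P(T=0, Y=j) = Φ₂(a_j, −c; ρ) − Φ₂(a_{j−1}, −c; ρ)
    P(T=1, Y=j) = [Φ(a_j) − Φ₂(a_j, −c; ρ)] − [Φ(a_{j−1}) − Φ₂(a_{j−1}, −c; ρ)]

This closed form is the default estimation route (exact, fast, analytic
gradients). Φ₂ is evaluated with Owen's T-function identity
(`scipy.special.owens_t`), vectorized; ρ = 0 is special-cased to the
exact product Φ(h)Φ(k) because the Owen identity's ~1e−16 *absolute*
accuracy translates into poor *relative* accuracy for near-zero cells,
which matters on the log scale.

A latent-factor form is provided for cross-validation and for users who
want the simulated-likelihood route: a shared factor η ~ N(0,1) enters
both equations with loadings λ_T = λ, λ_Y = sign(ρ)·λ, λ² = |ρ|/(1−|ρ|)
(the symmetric mapping covers all ρ ∈ (−1,1); conditional on η the two
equations are independent). The η-integral is taken either by
Gauss–Hermite quadrature or over a Halton point set. For the Halton
scheme the sorted points are used as a quadrature rule — midpoint-spacing
weights, nodes at each cell's truncated-normal centroid — rather than an
equal-weight average: measured against the closed form this reduces the
bias by roughly two orders of magnitude at 500 draws (max relative gap
~2e−4 across random parameter points with |ρ| ≤ 0.8, vs ~1e−3·|ℓ| for
equal weights, whose error decays only as 1/N). Gauss–Hermite with 64
nodes agrees with the closed form to ~1e−10 relative for |ρ| ≤ 0.8;
accuracy of both integration schemes degrades as |ρ| → 1 because the
loadings diverge.

### Optimization and inference

Parameters are maximized unconstrained via BFGS with analytic gradients:
cutpoints as (μ₁, log-gaps), ρ on the atanh scale. Starting values come
from the two separate fits (probit for T, ordered probit for Y including
the treatment dummy) with ρ₀ = 0. Convergence requires BFGS success or a
gradient sup-norm below 1e−5·|ℓ| (BFGS can stop on line-search precision
loss with a gradient whose implied parameter step is far below any
standard error). Standard errors come from the inverse observed Hessian
(central finite differences of the analytic gradient) with the delta
method back to the (μ, ρ) scale. A first-stage Wald statistic on the
exclusion restrictions below 10 per restriction triggers a
weak-identification warning.

The binary probit restricted model is fit through
`statsmodels.discrete.Probit`; the ordered probit is implemented
in-package (it shares the cutpoint parameterization and likelihood
kernel with the joint model, and has no intercept by design), with
statsmodels' `OrderedModel` serving as an independent cross-check in the
test suite.

### LR test of error independence

H₀: ρ = 0. Because the ρ = 0 likelihood factorizes exactly into the
probit and ordered-probit likelihoods, the restricted maximum is the sum
of the two separate fits' maxima, and

    LR = 2(ℓ_joint − ℓ_probit − ℓ_oprobit) ~ χ²(1).

Small negative statistics (joint optimizer short of the restricted sum)
are clipped to zero with a warning beyond −1e−4.

### Marginal treatment effects

The MTE is the treatment contrast for individuals indifferent between
treating and not: latent treatment index exactly zero, v = −c. Then
ε | v = −c ~ N(−ρc, 1−ρ²), and

    effect_j = Φ((a_j(1)+ρc)/s) − Φ((a_{j−1}(1)+ρc)/s)
             − [same with t=0],   s = √(1−ρ²)

averaged over the full estimation sample. The four category effects sum
to zero identically (exhaustive partition). Confidence intervals are
percentile bootstrap: resample rows, refit the joint model warm-started
at the full-sample estimates, recompute the average; non-converged
replicates are dropped and counted, with an error above 20% failures.
The percentile construction was chosen because it is the standard
distribution-free default; asymmetric intervals are expected when ρ̂ is
near its boundary.

## Synthetic data

The generator emulates the structure of a German general-social-survey
analysis sample (n = 3471): binary/categorical covariates drawn
independently at the published marginal frequencies, a smoking-prevalence
instrument drawn truncated-normal with gender-specific moments
(30.0 ± 2.5 for men, 20.6 ± 2.0 for women, truncated at 0), and (T, Y)
from the structural model with the published coefficient values as
ground truth (treatment effect δ = 1.155, cutpoints (−1.805, 1.033,
2.495)) and ρ = −0.5 by default.

Two calibrations close the gaps the publication leaves open. The
treatment intercept (not reported) is solved numerically so the implied
smoking share is 28.8%. The cutpoint *location* is likewise shifted so
the model-implied P(BMI class ≤ 2) matches the printed 45.9% — the
published cutpoints presume the survey's own latent-index distribution,
and without the shift the underweight class all but vanishes under
independently drawn covariates. Both calibrated constants are recorded
in every scenario manifest.

What the generator does **not** emulate: the joint covariate
distribution (only margins; real food-frequency items correlate with
gender and each other), the two-stage municipality sampling design,
item nonresponse patterns, and the exact spread of the latent index —
the simulated underweight share (~0.2–0.3%) stays below the printed
2.0%. Consequently, passing recovery tests show the estimator is correct
under the model; they do not show the model fits any particular real
dataset.

Named scenarios: `paper` (ρ = −0.5), `null` (ρ = 0), `strongrho`
(ρ = −0.8), `weakiv` (all exclusion-restriction coefficients zero —
genuinely unidentified, triggers the first-stage warning). A compact
design (two outcome covariates, same three exclusion restrictions)
backs repeated-fit studies where speed matters.

## Validation studies and problem sizes

The suite's end-to-end checks, with the sizes chosen for them:

- **Printed-count descriptives.** Pearson chi-squares recomputed from
  the published gender cross-tabs reproduce 94.948 (BMI), 77.825
  (marital status) and 12.879 (education); shares reproduce 44.0% /
  36.0% / 28.8% on their per-variable denominators. No continuity
  correction — with it the published values are not recovered. Two
  published statistics are *not* asserted: the smoking×gender chi-square
  (printed 35.717, recomputes to 35.456 from the printed cells,
  consistent with unreported item missingness) and the smoking-prevalence
  t (printed 62.193; Welch and pooled forms both give ≈122 from the
  printed moments, so the printed test's construction is unknown).
- **Oracle equivalence.** 50 random parameter points, data of n = 200
  generated from each point (so realized cells are typical), closed vs
  GH-64 within 1e−6 relative and vs Halton-500 within 1e−3 relative.
- **ρ = 0 separability** to 1e−10 at matched parameters.
- **Recovery under endogeneity.** 20 generator seeds at n = 20 000 with
  the published coefficients as truth and ρ = −0.5: the mean δ̂ lands
  within 0.05 of 1.155, every run within 3 SEs, and the naive ordered
  probit's smoking coefficient is attenuated in every run.
- **LR size.** 500 replicates at n = 3400 under ρ = 0 on the compact
  design at reduced optimizer tolerance: empirical rejection at the 5%
  level within 0.05 ± 0.02.
- **MTE structure.** Zero-sum identity, δ = 0 limit, conditional
  Monte-Carlo cross-check at the margin, and — at the published
  parameters — a positive obese effect and negative normal-weight effect
  in both gender strata.

## Known limitations

- Independent covariates understate design-matrix collinearity relative
  to real survey data; standard errors on synthetic data are therefore
  somewhat optimistic.
- The simulated underweight class is thin; stratified fits at n ≈ 1700
  occasionally realize no underweight smokers, in which case cutpoint
  μ₁ is weakly determined (fits still proceed; a warning is emitted).
- Quadrature/QMC likelihood accuracy degrades for |ρ| ≳ 0.9; the closed
  form has no such restriction and is the default.
- The bootstrap refits warm-started at the full-sample optimum; with
  severely weak instruments the 20% failure guard will trip, which is a
  feature, not a bug.
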