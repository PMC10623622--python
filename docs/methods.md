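# Methods

## Models

Observed variables are the responses `Y_it` of each respondent to items
i = 1..I at occasions t = 1..T, arranged item-major within occasion
blocks; all moment matrices follow that fixed ordering. Two
measurement models are implemented.

**Multi-state model (states_only).** One latent state `eta_t` per
occasion, congeneric items with strong (scalar) invariance: loadings
`lambda_i` and intercepts `alpha_i` constant over time, reference item
fixed at `lambda_r = 1`, `alpha_r = 0`. Free parameters: T state means,
T(T+1)/2 state (co)variances, (I−1) loadings, (I−1) intercepts, and
I·T residual variances — 32 for 5 × 3, giving test df 103.

**Item-effects model (item_effects).** All loadings fixed to 1 and all
intercepts to 0; besides the T states, each non-reference item carries
a time-constant latent difference variable `delta_i`, so
`Y_it = eta_t + delta_i + eps_it` with `delta_r = 0`. The m = T + I − 1
latent variables have free mean vector κ and unrestricted covariance
Φ; residual variances are free per item × occasion and residual
covariances are zero — that residual structure is what yields 50 free
parameters and df 85 for 5 × 3, matching the df bookkeeping of the
published analysis this package's defaults emulate. T ≥ 3 is enforced:
with two occasions the variance of a time-constant item effect is not
separable from occasion-specific residual variance.

Both variants, and the structural extensions below, are instances of
one internal moment structure `mu = alpha~ + Lambda kappa`,
`Sigma = Lambda Phi Lambda' + diag(theta)` with fixed and (possibly
tied) free cells in `Lambda` and `alpha~`.

## Identification and the reference switch

The reference item defines what the states *mean*; the choice cannot
affect fit. Switching reference r → s is the exact linear latent map

    eta'_t  = eta_t + delta_s,
    delta'_i = delta_i − delta_s  (i ∉ {r, s}),
    delta'_r = −delta_s,

applied as κ' = Aκ, Φ' = AΦA'. It preserves the implied observed
moments identically, is an involution (switching back restores the
original table to machine precision), and transforms the parameter
covariance by the same linear map, so Wald flags remain available
after switching. The package applies the map to any latent moment
table, including tables assembled from printed estimates.

## Estimation

Complete-case ML minimizes the normal-theory discrepancy
`F = ln|Sigma| + tr(S Sigma^-1) − ln|S| − p + (ybar−mu)' Sigma^-1 (ybar−mu)`
(equivalently maximizes the multivariate-normal likelihood; the
identity −2ℓ = N(F + ln|S| + p + p·ln 2π) is asserted in the tests).
FIML maximizes the casewise likelihood over each respondent's observed
subvector, implemented on per-missingness-pattern sufficient
statistics so that cost is independent of N once moments are computed;
complete data is the single-pattern special case, making FIML ≡ ML
there by construction. Listwise deletion is an explicit preprocessing
option mirroring complete-case analyses.

Free parameters are optimized unconstrained: Φ through its Cholesky
factor with log diagonal, residual variances through logs — every
iterate is admissible by construction. Gradients are analytic
(per-pattern accumulation of dF/dΣ and dF/dμ, chained through the
loading/covariance structure). The optimizer is L-BFGS-B from
deterministic method-of-moments starts (state moments from the
reference item's cross-occasion covariances; item-effect moments from
item-minus-reference contrasts; residual variances at half the
observed variances). Because L-BFGS-B occasionally declares an
objective-change stop on a plateau, the driver restarts it from the
last iterate and, if a residual gradient remains, finishes with damped
Newton steps in the natural parameterization using the analytic-
gradient finite-difference Hessian. Convergence requires a scaled
gradient ∞-norm below 1e−5 (cap 500 iterations per L-BFGS pass);
non-convergence is flagged on the result, never raised. There is no
randomness anywhere in estimation.

Standard errors invert the observed information, computed as the
Hessian of −ℓ at the estimate in the natural parameterization
(κ, vech Φ, free loadings/intercepts, θ) by central differences of the
analytic gradient. A singular information matrix raises an error
naming the flattest direction. Latent SDs and correlations get
delta-method SEs; correlation tests use the Fisher-z transform. Means
are tested by plain Wald z; variances by a Wald z on the variance
itself (a log-scale variance test cannot represent the boundary null
of zero variance, so the plain Wald form is used and flagged at
α = .05 like everything else).

## Fit statistics

The model χ² is N·F at the estimate (an N−1 multiplier is available;
both reproduce the published RMSEA worked examples at 3 decimals).
For FIML fits the χ² is the likelihood-ratio statistic against a
saturated model estimated by EM on the same pattern moments. RMSEA
uses the classic `sqrt(max(χ²−df,0)/(df(N−1)))` with a 90% CI from
inverting the noncentral-χ² cdf in the noncentrality parameter
(bracketed bisection to 1e−8). SRMR is the root mean square of
standardized covariance residuals over the p(p+1)/2 lower-triangle
cells; mean residuals are excluded because the item-effects model
saturates the mean structure. CFI/TLI use the independence baseline
with free means and variances (closed form for complete data,
optimized casewise under FIML — the baseline an ML-normal analysis
conventionally adopts). AIC = −2ℓ + 2q, BIC = −2ℓ + q·ln N. The
good/acceptable classifier applies the conventional cutoffs
(.97/.97/.05/.05 and .95/.95/.08/.10).

## Outcome regressions

A manifest composite Z (scored as the mean of available item
responses) is appended to the observed vector and regressed on a
predictor subset of the latents inside one simultaneous ML fit:
`Z = nu + gamma' zeta + eps_Z`. R² = γ'Φγ / (γ'Φγ + ψ) and
standardized coefficients use the model-implied SD of Z. The full
predictor set spans the same space under every reference item, so its
R² is reference-invariant; the states-only R² is not — the ΔR²
credited to item effects is therefore a statement *about a particular
reference*, which is the substantive point of the analysis. Structural
fits start from a converged measurement fit plus an OLS regression of
Z on regression factor scores; the joint ML fit then refines both
parts. Standardized coefficients above 1 in magnitude (possible under
the strong collinearity of item-effect variables) set a flag on the
result. Multiple outcomes are analyzed in separate models.

## Synthetic data

The generator draws latents from N(κ*, Φ*) and composes responses
through the item-effects measurement model — the generative model *is*
the analysis model, which is what makes the χ² calibration and
recovery suites meaningful. The default truth κ*, Φ* equals published
SWLS latent moments from a large Dutch probability panel (reference
item 3, 2008–2010 period, N = 2,543): state means ≈ 5.5, SDs ≈ 1.0,
state correlations .70–.79; item-effect means −0.28 to −0.99, SDs
0.39–0.89. Default residual variances are 0.35 per item (0.30 for
item 5), constant over occasions in the generator though freely
estimated per item × occasion when fitting; they place all implied
observed item SDs (1.14–1.43) inside the 1.08–1.63 range reported for
the instrument. Outcome composites are linear in the latents with
standardized weights taken from the published full-model regressions
(distress composite: mean 2.20, SD 0.82; mobility composite: mean
1.20, SD 0.34), then optionally passed through a monotone exponential
transform that induces right skew while preserving the target mean and
SD exactly in population. Responses are continuous by default: the
analysis model is linear-normal, and rounding to the 1–7 scale
(`discretize=True`) is a deliberate model-mismatch mode. Missingness
is wave-level MCAR unit nonresponse; a respondent always keeps at
least one wave. All randomness flows through one
`numpy.random.default_rng(seed)` (PCG64), so outputs are reproducible
bit-for-bit across runs and platforms.

What the generator does *not* emulate: ordinal response scales (unless
discretized), floor/ceiling effects, MNAR nonresponse, panel
refreshment, sampling weights, or time-varying item effects. Passing
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness of the substantive findings to
violations of them.

## Problem sizes in the test suite

The simulation suites run at N = 2,000 (equivalence, recovery — 100
replications, χ² calibration — 500 replications), N = 1,000 with 30%
wave nonresponse (FIML bias, 100 replications), and N = 5,000 (null
ΔR², 31 replications); these sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping the suite quick on one core.

## Known limitations

- No robust (sandwich) or scaled test statistics; normal-theory only.
- FIML fit indices depend on an EM-estimated saturated model; with
  pathological missingness patterns EM may converge slowly.
- Boundary solutions (zero residual variance, singular Φ̂) are flagged
  or raise at extraction rather than being prevented; small samples
  with weak item effects can produce them.
- Ordinal/categorical estimation (polychoric, WLSMV) is out of scope;
  7-point responses are treated as continuous.
- The two-period "cross-validation" driver runs independent analyses
  per period; it does not model cross-period dependence of the same
  respondents.
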