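# Methods

## The model family

All six families share the NB kernel in mean/overdispersion form,

    P(y | η, α) = C(1/α + y − 1, y) (1/α / (1/α + η))^{1/α} (η / (1/α + η))^y,

with mean η and variance η + αη². The log link λ_it = exp(β X_it + £)
carries the covariates; the literature often writes an extra multiplicative
Gamma(1, α) error ε in this link, but that Gamma mixing is exactly what
turns a Poisson into the NB kernel above, so the package treats the NB pmf
as the likelihood primitive and introduces no separate ε latent — adding
both would count the same overdispersion twice.

The mixing layers multiply the NB mean by a positive variable:

- **Lindley** (families NB-L, α-RENB-L, £-RENB-L, RPNB-L):
  f(τ; θ) = θ²/(θ+1) (1+τ) e^{−θτ}, mean (θ+2)/(θ(θ+1)). Sampled through
  its exact augmentation τ ~ Gamma(1+χ, θ), χ ~ Bernoulli(1/(1+θ)) — the
  (shape = 1+χ, rate = θ) reading is the only one whose marginal matches the
  density above.
- **Generalized Exponential** (NB-GE): f(Λ; ω, v) = ωv(1−e^{−ωΛ})^{v−1}e^{−ωΛ},
  mean (ψ(v+1) − ψ(1))/ω, sampled by inversion Λ = −log(1 − U^{1/v})/ω.

Heterogeneity variants randomize one layer per observation: the
overdispersion (j = 1/(1+α_it) ~ Beta(a, b)), the intercept
(£_it ~ N(c, d)), or the regression coefficients (β_it = β + w_it,
w_it ~ N(0, σ²), independently per observation; a per-segment-shared option
is deliberately not the default because the hierarchy indexes the deviations
by both segment and period).

## Priors

Gamma priors are (shape, rate) throughout. Regression coefficients and the
fixed intercept get N(0.01, variance 10000) — the variance reading, since a
precision of 10000 would be a near-point mass and contradict the prior's
diffuse purpose. θ ~ Gamma(0.3, 0.5); ω, v ~ Gamma(0.01, 0.01);
j's hyper-parameters a, b ~ Gamma(1, 0.1); the random-intercept hypermean
c ~ N(0, 100) and hypervariance d ~ Inv-Gamma(2, 1); random-coefficient sds
σ ~ half-normal(scale 2), weakly informative so the sign-share computation
stays stable.

The global α has no stated prior in the source conventions, so the package
default is Gamma(1, 0.01) — an Exponential with mean 100, finite at zero and
effectively flat over the plausible range. A shape below 1 (the common
Gamma(0.01, 0.01) choice) concentrates nearly all prior mass at numerically
tiny α and, in combination with per-observation mixing latents, makes a
degenerate Poisson exact-fit mode of the augmented posterior strongly
attractive; the shape-1 default removes that spike without adding
information anywhere the likelihood speaks. Every hyper-parameter is
overridable through `PriorConfig` and the run config.

## Identifiability: the mixing-scale ridge

The NB mean is η = m·exp(£ + βX). Rescaling the mixing law against the
intercept — m → s·m, £ → £ − log s — leaves every η unchanged, so the
likelihood constrains θ (or ω) and the raw intercept only through the
*shape* changes of the mixing law, and the Lindley shape interpolates merely
between Gamma(1, ·) and Gamma(2, ·). A profile of the exact marginal
likelihood (by quadrature) along the mean-matched θ ridge varies by less
than one nat over θ ∈ [0.04, 8] at 600 observations: θ, ω and the raw
intercept are practically unidentified individually; α participates
partially in the same complex. What the data pin down are the slopes and
the **mean-scale level** £ + log E[m], which the package exposes
(`recovery.level_draws` / `level` in scorecards) and which its recovery
studies score. Raw-coordinate columns are still reported, with the caveat
that their posteriors are prior-dominated along the ridge. Reported
single-chain estimates of θ with tight intervals — common in this model
class — are artifacts of samplers that never traverse the ridge.

## Sampler

Metropolis-within-Gibbs over the augmented joint:

- latent vectors (τ, Λ, j, £_it, w) update in one vectorized element-wise
  Metropolis step each (log, logit or identity scale as appropriate);
- χ has the exact conditional P(χ=1 | τ) = τ/(1+τ); c and d are conjugate
  (normal / inverse-gamma) and Gibbs sampled;
- global scalars use adaptive random walks; θ uses the sufficient-stat form
  of its conditional (the χ terms cancel to 2N·logθ − N·log(1+θ) − θΣτ);
- per-block proposal scales adapt toward 0.25–0.45 acceptance in windows of
  50 iterations during burn-in and freeze afterwards, preserving detailed
  balance in the sampling phase.

Two classes of structural moves make the ridge geometry tractable:

1. **Ridge moves.** (m, £) → (s·m, £ − log s) with s log-normal, and θ (or
   ω) updates that simultaneously rescale the mixing vector to keep its mean
   (hence every η) fixed, with the exact Jacobians of the deterministic
   transforms. For the GE layer the ω move is an exact scale-family
   reparameterization (the density terms cancel against the Jacobian).
   Without these moves chains cannot traverse the ridge and R-hat sticks
   near 1.5 on the intercept.
2. **Interweaved (centered) coefficient updates.** After each standard
   coefficient step, a second proposal moves β_k and the mixing vector
   jointly with η held fixed (m_it → m_it·e^{−δx_it}), judged by the mixing
   density alone. In the non-centered parameterization the per-observation
   latents can re-fit every positive count after a slope change, making
   slope moves second-order flat and metastable for >10⁴ iterations; the
   centered companion restores a first-order force (the
   ancillarity–sufficiency interweaving strategy).

Positive scale-type parameters are truncated to e^{±12} by proposal
rejection — an exact truncation of their priors. The ridge direction is
likelihood-invariant and only weakly tethered by the vague priors, so an
untruncated walk can reach numerically unrepresentable states; the box is
far wider than any data-supported range and leaves identified quantities
untouched.

Initialization is deterministic: coefficients at 0, positive parameters at
their prior means, χ at 0 — except α, initialized at 1 because its
vague-prior mean (100) is a poor starting point for any real panel.
Reproducibility: chain seeds derive from one `SeedSequence`; identical
config + seed gives identical draws.

MCMC caches only the mean-dependent part of the NB log pmf: for proposals
that hold the overdispersion fixed the Γ(1/α+y) terms cancel from every
Metropolis ratio, and the constants are restored only when the deviance is
recorded.

## Convergence and summaries

`gelman_rubin` computes the classic potential scale reduction factor
R̂ = sqrt((W + B/n)/W) over whole chains, which is exactly 1 for identical
chains and diverges for separated ones; the conventional threshold is 1.05.
(The rank-normalized split variant, available through arviz, is used as an
independent cross-check in the test suite.) Summaries report posterior
mean, sd, equal-tailed 95% intervals, and a significance flag (interval
excludes zero).

## Fit indices

DIC = D̄ + p_D with the conditional NB deviance given the mixing latents.
The plug-in point for p_D = D̄ − D(·) is the posterior mean of the
deviance's own continuous parameters — the NB mean surface η̄_it (which is
also the fitted value ȳ_it used by MAD and RMSE) and the overdispersion.
Averaging the mixing latents and the intercept separately instead is
incoherent under the scale ridge and can push p_D to large negative values;
the η-focused plug-in reduces to the same point whenever there is no ridge
(e.g. the NB family, where p_D ≈ the parameter count). MAD and RMSE are the
cell-averaged absolute and root-mean-square differences between ȳ and y;
RMSE ≥ MAD always.

## Synthetic data

The generator emulates the covariate structure of a real mountainous-freeway
study panel: 24 covariates with published means/sds/min-max (continuous,
truncated normal by rejection) or proportions (binary), 696 segments × 8
quarters. The bridge-proportion covariate is excluded: its published sd
(7.603) is impossible for a share bounded in [0, 1]. Counts are drawn
through the same augmentations the sampler uses, so simulation and
likelihood match exactly. The default truth uses the curvature and
special-segment covariates with their reported NB-L coefficients, the
reported Lindley θ = 2.576, and α = 0.63 with the intercept solved in closed
form (truncated-normal mgf) so the outcome mean hits the observed 0.746;
that calibration also reproduces the observed overdispersion (variance ≈ 1.9
against the observed 1.383² ≈ 1.91) and yields a ~63% zero share.

What the generator deliberately omits: within-segment persistence of design
covariates, seasonal autocorrelation of weather and traffic, spatial
adjacency, and covariate correlations (an optional correlation hook exists
for stress tests but the default is independence, as no correlation
structure is published). Passing recovery tests therefore show that the
estimators invert their own generative hierarchies — not that the real
panel satisfies those independence assumptions.

## Study sizes used by the tests

Stochastic test sizes are package choices fixed in advance: recovery
studies run 20 replicates per family at I = 150 segments × T = 4 periods
with 2 chains × 4000 iterations (burn-in 1500, thin 5), asserting ≥ 17/20
coverage and |bias| < 0.15 on the identified block (slopes + level); the
DIC-direction check runs 12 replicates at I = 200 × T = 8 with the ≥ 80%
threshold; oracle cross-checks use 3–4 × 10⁵ Monte-Carlo draws against
quadrature at 3 standard errors. The acceptance script uses 12 recovery
replicates per family and 10 DIC replicates.

## Known limitations

- θ, ω and the raw intercept are reported but prior-dominated along the
  scale ridge; only the level is a trustworthy location summary.
- Random coefficients are independent across observations; panels with
  segment-persistent heterogeneity will understate σ.
- DIC with conditional focus rewards latent fields generously (p_D ≈ 100 on
  a 600-cell NB-L fit); comparisons are meaningful within this fixed focus,
  which is used consistently for all six families.
- The α-RENB-L hyper-parameters (a, b) are weakly identified at desk-scale
  panel sizes; their posteriors shrink only slowly with n.
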