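# Methods

## The informative-sampling model

The simulator draws populations from a directed acyclic graph in which
observed covariates (age, gender) influence a latent binary health status,
and health drives both survey nonresponse and survival. Conditioning on the
effective sample (responders) opens a collider path between sampling and
survival, so unweighted and calibrated-survey-weighted survival estimates
are biased even though the planned sample is a simple random draw.

Components and defaults:

- **Age** ~ Uniform(15, 95) years; **gender** a fair coin. The generator
  makes no attempt to emulate a real age pyramid, regional strata,
  nationality or civil status — the downstream bias mechanism needs only
  covariates that predict health.
- **Health**: `logit P(poor) = β₀ + ln(2)·age_std + ln(1.5)·male`, with
  `age_std` standardized by the theoretical uniform moments and β₀ solved by
  bisection (tol 1e-8) so the marginal prevalence is exactly 0.2 by
  construction. The age/gender effect sizes and the prevalence are
  conventional "older men are sicker" magnitudes, exposed in
  `PopulationParams` so sensitivity is a one-line config change.
- **Survival**: exponential (constant hazard) with rate `λ₀·4^poor_health`;
  administrative censoring at τ = 1 time unit, mirroring a one-year
  mortality follow-up. λ₀ is calibrated by Brent root search so the marginal
  death fraction `(1-p)(1-e^{-λ₀τ}) + p(1-e^{-4λ₀τ})` hits the target (10%
  or 25%) to 1e-8; because the hazard depends on covariates only through
  health, this mixture is exact for any age/gender structure.
- **Nonresponse**: logistic in poor health only (the graph routes
  covariate effects on response through health), odds ratio 4, intercept
  solved so the expected nonresponse among the sampled equals the target
  (10% or 25%).

Randomness flows from a single seed through `numpy` `SeedSequence`
substreams per stage (ages, gender, health, survival, sampling,
nonresponse), so any stage can be re-run independently and every
replication is reproducible from `(base_seed, rep_index)`.

## Weights

**CS weights** use only what a statistical office could know:
`w = 1 / (f · p̂_resp)`, where `f` is the sampling fraction and `p̂_resp`
comes from a logistic response model in age and gender fitted among the
sampled (default), or the marginal response rate (`cs_response_model=
"marginal"`). With the marginal rate, CS weights are constant and exactly
equal the unweighted analysis; the covariate-based default partially
corrects the bias (age and gender proxy health) without ever seeing health
itself, which is the realistic nonresponse adjustment. An `"oracle"` mode
conditioning on the latent health exists purely for contrast.

**IP weights** are `1 / p̂` from a logistic model of effective-sample
membership fitted on the **full** population. The simulation default
conditions on age, gender, vital status, the Nelson–Aalen cumulative hazard
evaluated at each individual's exit time, and age/gender × survival
interactions — the same structure the real-data model uses. The
cumulative-hazard term matters: conditioning on vital status alone
calibrates weighted death counts but not weighted person-time, leaving a
small (order 1e-3) negative residual in the log rate; adding the
Nelson–Aalen term removes it. Weights are unstabilized Horvitz–Thompson
reciprocals by default, since the targets are population-level totals and
rates; stabilization and percentile truncation are options (off by
default — weight diagnostics are always returned).

## Estimators

Crude participation odds ratios take participation odds against
**non-participants** (population minus participants), with Wald CIs on the
log scale and the 1.96 quantile fixed; this is the convention that
reproduces the published table to its printed rounding, and it is verified
against a single-covariate logistic fit to 1e-6.

Weighted Poisson rates use the closed form `Σ w·d / Σ w·t` per stratum
(equal to the offset-GLM MLE in a saturated model, verified to 1e-8), with
sandwich variance `Σ w²(d - r·t)² / (Σ w·t · r)²` for non-unit weights,
reducing to the `1/D` Poisson variance for unit weights. Rates are per
person-year internally and scaled (per 1,000) only for display.

## Censored skew-normal life expectancy

Ages at death are modelled as `SN(ξ, ω, α)`; mortality is left-skewed so α
is expected negative. The weighted log likelihood per record is
`w·[d·ln f(exit) + (1-d)·ln S(exit) - ln S(entry)]`; the entry term
conditions on survival to the entry age (delayed entry / left truncation).
Numerics:

- survival via the Owen's-T identity `S = Φ(-z) + 2T(z, α)` (exact, fast),
  clipped at the smallest positive double before taking logs;
- optimization by L-BFGS-B on `(ξ, ln ω, α)` with shape starts
  α ∈ {-5, -1, 0} (location/scale starts from the weighted moments of the
  uncensored deaths, shifted by the skew-induced mean offset); the direct
  parameterization with multi-start proved robust across the tested
  regimes, so no centred reparameterization is used — the α ≈ 0
  information singularity affects standard errors near zero skew, not the
  point fit, and the `fix_alpha=0` profile covers the normal reduction;
- weights are normalized to mean one inside the fit, making estimates
  exactly invariant to the weight scale; |α| is capped at 25 and boundary
  solutions are flagged, never silently returned;
- covariance by the sandwich `A⁻¹BA⁻¹` (weights are sampling weights, not
  frequency weights) from numerically differentiated scores, mapped to the
  `(ξ, ω, α)` scale;
- remaining life expectancy `LE(a) = ∫ₐ S dt / S(a)` by adaptive quadrature
  to 1e-8 with upper limit ξ + 10ω (extended when the tail mass beyond it
  exceeds 1e-10); CIs by the delta method over the fitted covariance.

A fit requires at least 50 uncensored deaths by default (configurable); the
α = 0 reduction is cross-checked against an independent censored-normal
MLE and against R's `survival::survreg(dist = "gaussian")`.

## Simulation study and problem sizes

The full study design crosses death fraction {10%, 25%}, sampling fraction
{1%, 10%} and nonresponse {10%, 25%} — eight scenarios — regenerating the
population each replication (a fixed-population mode exists for variance
decomposition). Comparisons are on the log-rate scale; replications with no
(weighted) deaths are flagged and excluded with counts reported. Ellipse
summaries use the coordinate-wise mean and the 2×2 sample covariance at the
χ²₂ 0.95 quantile (5.991).

The package's default runs are scaled down from the reference design of
1,000,000-person populations and 1,000 replications: the test suite and the
acceptance script use populations of 100,000 with 200 replications for the
headline scenario and 100 per grid cell, which keeps Monte Carlo standard
errors small enough to resolve every qualitative claim while completing in
minutes on one CPU. Replication counts and population sizes are plain
configuration for larger runs.

## What the synthetic data does and does not show

The generator reproduces the *mechanism* of informative sampling — a latent
confounder between nonresponse and survival — under clean conditions:
exponential survival, logistic health and response models, independent
sampling. Passing tests demonstrate that the estimators recover truth when
their assumptions hold and that CS-style weighting cannot, by construction,
remove outcome-side selection. They do not demonstrate robustness to
real-data features the simulator omits: non-uniform age pyramids,
regionally stratified sampling, household clustering, time-varying hazards,
or misspecified participation models whose covariates fail to capture the
selection (in the real analysis, exchangeability given the modelled
covariates and survival information remains an untestable assumption). The
bundled synthetic census (`make_synthetic_census`) is likewise a labelled
stand-in with invented frequencies, used to exercise the census-schema
pipeline, not to emulate any real population.

## Known limitations

- The real-data life-expectancy validation requires the anonymized
  supplementary dataset, which must be supplied by the user at
  `data/SwissCensus2010.csv`; only its schema and pipeline are testable
  offline.
- The participation model is design-based; model-based (outcome-regression)
  alternatives are out of scope.
- Life-expectancy CIs are delta-method; no bootstrap is implemented.
- The skew-normal model is intercept-only and fitted per stratum (the
  reference analysis fits men and women separately); covariates enter
  through stratification, not through a linear predictor on the location.
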