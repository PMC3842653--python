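# Methods

## Model

Daily ED visit counts y_ij for region j on day i are modeled as
Binomial(n_ij, p_ij) with a logistic link and an additive predictor

    logit(p_ij) = β₀ + Σ_k β_k x_ijk + Σ_m f_m(x_ijm),

where the x_ijk are linear and 0/1-indicator covariates (lag-weighted fire
PM, demographic proportions, weekday and region flags) and the f_m are
nonlinear functions: a univariate smooth of anthropogenic PM₂.₅ and a
bivariate humidity × minimum-temperature surface. Binomial denominators are
the fixed regional census populations — counts and trials, not offsets — so
p_ij is the per-person daily probability of an ED visit and exp(β) terms are
odds multipliers.

### Spline machinery

Univariate smooths use the truncated-power natural cubic spline basis
{1, x, N₃…N_K} with knots at quantiles of the unique covariate values;
functions are linear beyond the boundary knots. The roughness penalty is the
Gram matrix of ∫ f″(x)² dx, computed exactly by per-interval Simpson
quadrature (natural-spline second derivatives are piecewise linear, so the
integrand is piecewise quadratic). Constants and straight lines span the
penalty null space.

The bivariate surface is a tensor product of two marginal natural cubic
bases (recommended practice when the two covariates carry different units,
as % humidity and °F do) with one penalty per margin, Ω_a⊗I and I⊗Ω_b, so a
surface additive in one margin is not penalized through the other.

Identifiability: each smooth's constant basis column is dropped and the
remaining columns are centered to sum to zero over the observed covariate
values; the intercept carries the level. Default basis sizes are 10 for the
univariate smooth and 5×5 for the tensor — enough flexibility for the
saturating and ridge-shaped effects of interest at n ≈ 121–726 while keeping
the fit fast; results are insensitive to moderate increases.

### Fitting and smoothing selection

Penalized IRLS with working weights n_ij p(1−p), converged when the relative
deviance change falls below 1e-8 (cap 100 iterations; non-convergence is
flagged, never silent). A linear predictor walking past ±30 means fitted
probabilities pinned at the floating-point boundary; this is diagnosed as
separation and raised as an error rather than returned as huge coefficients.

Each penalty's smoothing parameter minimizes the deviance-based GCV score
n·D(λ)/(n − edf(λ))² with γ = 1. Penalty matrices are first rescaled to the
Frobenius norm of their block of the initial information matrix XᵀWX, which
makes the search grid scale-free in the covariate units (without this, a
penalty expressed in (°F)⁻⁴-like units needs λ far outside any fixed grid).
The search is coordinate-wise over a 30-point log₁₀λ grid on [−6, 6], two
sweeps, warm-starting the IRLS at each step, followed by a bounded
golden-section refinement of each coordinate inside its winning grid
bracket. Effective degrees of freedom are block traces of
(XᵀWX + S_λ)⁻¹XᵀWX.

With no smooth terms the machinery reduces exactly to an unpenalized
logistic GLM; the test suite verifies agreement with statsmodels' GLM to
better than 1e-6 relative in coefficients and standard errors.

### Inference

Coefficient covariance is the Bayesian (penalized) form (XᵀWX + S_λ)⁻¹,
used for Wald tests of linear terms, pointwise 95% bands (±1.96 se) on
centered smooths, and delta-method standard errors on the response scale
(se_p = p(1−p)·se_η). Smooth and tensor terms are tested with a
rank-truncated Wald statistic evaluated on the fitted function values: the
statistic f̂ᵀV_f^{r−}f̂ uses the leading r eigencomponents of
Cov(f̂) = B V Bᵀ with r = rounded edf (min 1), referred to χ²_r. Working in
function space rather than raw coefficient space matters: the leading
eigendirections of the coefficient covariance are the *least* informed
combinations, and truncating there discards precisely the directions the
data estimate well. Under a null smooth the test's measured type-I rate at
α = 0.05 is ≈ 0.05–0.08 (200 simulations).

Known limitation: smoothing-parameter selection is not propagated into the
covariance, so standard errors of terms that compete with the smooths are
mildly optimistic (observed z-score dispersion ≈ 1.1–1.2 in the recovery
study) — the usual behavior of GCV-selected GAMs without a
smoothing-uncertainty correction.

## Exposure construction

* **Lag kernel.** Weights ∝ exp(−k²/(2σ²)) at lags k = 0…L, normalized; σ =
  1 day. The truncation L = 3 matches the three-day plume-transport horizon
  of the upstream dispersion modeling and is configurable. At the series
  start the available weights are renormalized (rather than zero-padding) so
  early days are unbiased and constants are preserved exactly.
* **IDW.** Great-circle (haversine) distances, default power 2 (the exponent
  is conventional, not derived); a target within 1 m of a station returns
  that station's value exactly.
* **Aggregation.** Population-weighted means over member zips; aggregation
  and the lag kernel are both linear, so their order does not matter (tested
  numerically).
* **Concurvity screen.** The fire PM₂.₅ and PM₁₀ channels are nearly
  proportional over short transport distances. The screen uses plain Pearson
  correlation at threshold 0.95 — a pragmatic surrogate for full concurvity
  diagnostics, adequate because the merge decision only needs to detect
  near-proportionality; PM₁₀ is retained (it contains PM₂.₅, keeping the
  particle mass unambiguous), and a constant (degenerate) pair is merged
  with a flag.

## Model selection

Backward elimination at α = 0.05, one action per step, deterministic (ties
in p broken lexicographically): each round first demotes any univariate
smooth whose 95% band admits a straight line — feasibility of
lower(g) ≤ a + b·g ≤ upper(g) on a ≥50-point grid, solved as a linear
program in (a, b) — then removes the single least-significant term with
p > α. Demotion precedes removal so a genuinely linear effect is kept as
linear rather than discarded; tensor terms are tested as a unit and never
demoted; the intercept is never removed. A refit failure is recorded in the
trace rather than raised mid-procedure.

## Synthetic data

The generator emulates the study season's structure (121 days, one county or
six sub-regions) so the whole pipeline is testable without restricted health
records. One seed drives named substreams (fire, weather, anthro, counts,
stations), making covariates and counts jointly reproducible bit-for-bit.

* **Fire PM:** near-zero lognormal baseline (median ≈ 0.1 μg/m³ at county
  scale) plus episodic bursts on configured days (defaults: day 21 and day
  82, mirroring the mid-August and late-October burn spikes). Each burst is
  a lognormal peak with exponential decay at 0.5/day; the main peak is the
  region's target maximum, and the secondary peak is sized so the series
  mean matches the region's target mean in expectation. This reproduces the
  heavy-tailed marginals (mean ≈ 12, SD ≈ 4–6× the mean, median ≈ 0.1).
* **Weather:** centered seasonal sinusoid (declining temperature, rising
  humidity into fall) plus shared county-scale and region-specific AR(1)
  noise; episode windows get a Santa Ana-like anomaly (humidity × 0.35,
  temperature + 4 °F, decaying over three days), producing the negative
  humidity–temperature coupling around fire days and the observed dry
  extremes. Values are clipped to [0, 100] % and [20, 110] °F.
* **Anthropogenic PM₂.₅:** lognormal AR(1) with φ = 0.7, moment-matched to
  each region's target mean/SD, clipped to [0.05, 3.5] μg/m³.
* **Demographics:** fixed per-region proportions (no daily variation).
* **Truth:** sub-region-scale defaults — intercept −7.76, fire-PM log-odds
  ln(1.00093)/μg/m³ applied to the *lag-weighted* exposure, Monday
  ln(1.174), Tuesday ln(1.072), region indicators ln(0.512)/ln(1.209),
  income ln(0.0087) and age ln(5.584) per unit proportion. The nonlinear
  truth is a saturating anthro-PM effect (linear rise to 1.2 μg/m³, then a
  plateau — so the linearity test has a genuinely nonlinear target) and an
  inverse-relationship humidity/temperature ridge whose maximum sits at high
  humidity and moderate temperature. Both are centered against a pooled
  reference sample drawn from the generating mixture itself (fixed internal
  seeds), which keeps the intercept identifiable; centering against a single
  county-scale marginal instead leaves a visible intercept bias because the
  six regions' covariate distributions differ.
* **Populations:** the binomial denominators are not public; defaults are
  calibrated as n_j = target mean visits / expit(baseline log-odds of
  region j), where the baseline includes the region's indicator and
  demographic contributions. This yields ≈ 0.4–0.9 million per sub-region,
  ≈ 3 million county-wide — consistent with the county's actual population,
  i.e. the published coefficient scale is compatible with realistic
  denominators. Calibrating from the intercept alone would miss the
  regional count levels by up to ~9× because the demographic terms shift
  the baseline log-odds by −2.6 to −1.4.

What the generator does **not** emulate: plume spatial structure within
regions, reporting gaps/vacation effects, overdispersion beyond binomial,
day-of-year confounding beyond one seasonal harmonic, and
errors-in-variables in the exposure. Passing tests therefore demonstrate
the statistical machinery is correct and well calibrated under the stated
generating process — not that real surveillance data meet these
assumptions.

## Validation studies (problem sizes)

Chosen to give stable rates at interactive run times on one CPU: GLM-oracle
comparison on 20 random small datasets; coefficient-recovery coverage over
100 seeded seasons (6 regions × 121 days each, full correctly specified
GAM); noise-covariate removal and linear-smooth demotion over 100
county-level seasons; smooth-test type-I calibration over 200 null
simulations; out-of-sample GCV-vs-linear comparison over 50 splits. The
full suite runs in roughly a minute; `scripts/acceptance.py` reruns the
same studies from a single seed.

## Numerical choices

IRLS tolerance 1e-8 (relative deviance), probability clipping at 1e-12,
weight floor 1e-12, separation threshold |η| > 30 at convergence, GCV grid
log₁₀λ ∈ [−6, 6] × 30 points with two coordinate sweeps plus bounded
refinement, rank cutoffs at 1e-10 of the largest eigenvalue, 95% bands at
±1.96 se, reporting rounded to 2 decimals (odds) and whole percent.
Degenerate inputs are errors, not warnings: zero/negative populations,
counts above trials, non-0/1 indicators, rank-deficient designs,
out-of-range episode days, proportions outside (0, 1).
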