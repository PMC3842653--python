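# firegam

A penalized binomial-logistic generalized additive model (GAM) pipeline for
estimating how wildfire particulate matter (PM) affects respiratory
emergency-department (ED) visits, built around the data structure of
syndromic-surveillance count series: daily ED visit counts per geographic
region with population denominators, modeled fire-PM concentrations,
anthropogenic PM₂.₅, weather, and demographics.

It is written for epidemiologists and air-quality modelers who need the full
chain from exposure construction to odds-effect reporting:

* **Exposure construction** — a truncated half-Gaussian cumulative-lag kernel
  (mode at lag 0, sd 1 day, 3 lags by default) applied to the fire-PM series;
  inverse-distance-weighted interpolation of station weather to zip
  centroids; population-weighted aggregation to model regions; and a
  concurvity screen that collapses the fire PM₂.₅/PM₁₀ pair into a single
  variable when their profiles are statistically indistinguishable.
* **A from-scratch penalized binomial GAM** — counts y_ij from region j on
  day i are Binomial(n_ij, p_ij) with

  ```
  logit(p_ij) = β₀ + Σ_k β_k x_ijk + Σ_m f_m(x_ijm)
  ```

  where the f_m are natural cubic spline smooths (and a humidity ×
  temperature tensor-product surface) with integrated-squared-second-
  derivative penalties, fitted by penalized IRLS; each smoothing parameter λ
  minimizes the deviance-based GCV score n·D/(n − edf)².
* **Model selection** — backward elimination at α = 0.05 with the
  confidence-band linearity rule: a smooth is demoted to a linear term when
  some straight line fits entirely inside its pointwise 95% band (a linear
  program in intercept and slope).
* **Odds-effect reporting** — coefficients transformed to multiplicative
  odds effects over each predictor's observed dynamic range, surface exports
  on the odds scale, and deviance-residual diagnostics.
* **A seeded synthetic-data generator** — the original health records are
  restricted, so the package generates 121-day seasons for one county / six
  sub-regions with episodic heavy-tailed fire-PM bursts, Santa Ana-like hot-
  dry weather anomalies, and binomial counts from a known truth, making
  every stage testable end to end.

## Worked example

```python
from firegam import RunConfig, SyntheticConfig, run_pipeline

cfg = RunConfig(seed=1, synthetic=SyntheticConfig(seed=1),
                level="subregion", out_dir="results/demo")
bundle = run_pipeline(cfg)
print(f"deviance explained: {bundle['summary']['deviance_explained']:.3f}")
print(bundle["effects"].to_string(index=False))
```

prints (seed 1):

```
deviance explained: 0.814
                term       role  range_lo   range_hi  odds_lo  odds_hi  percent_change
           intercept  intercept       NaN        NaN      NaN   0.0004             NaN
             fire_pm continuous  0.012456 388.791114     1.00   1.3800             NaN
   prop_income_gt50k continuous  0.300000   0.550000     0.25   0.0800             NaN
       prop_age_lt24 continuous  0.320000   0.410000     1.76   2.0700             NaN
           is_monday  indicator  0.000000   1.000000     1.00   1.2000            20.0
          is_tuesday  indicator  0.000000   1.000000     1.00   1.0600             6.0
         is_saturday  indicator  0.000000   1.000000     1.00   0.9600            -4.0
              is_sr3  indicator  0.000000   1.000000     1.00   0.5200           -48.0
              is_sr6  indicator  0.000000   1.000000     1.00   1.1900            19.0
      s(anthro_pm25)     smooth       NaN        NaN      NaN      NaN             NaN
te(mean_rh,min_temp)     tensor       NaN        NaN      NaN      NaN             NaN
```

Reading the table: the baseline odds of an ED visit on a given day are
exp(β̂₀) ≈ 4×10⁻⁴; at the peak lag-weighted fire-PM exposure observed in
this season (≈389 μg/m³) the odds are multiplied by 1.38; Mondays raise the
odds by ~20%; the SR3 indicator roughly halves them. (`is_saturday` survives
selection on this seed by chance at α = 0.05.) Smooth terms carry no single
multiplier — their odds-scale curves and the humidity/temperature surface
are exported as grids (`surface_*.csv`). The generating truth behind this
run used a fire-PM odds ratio of 1.00093 per μg/m³ and a Monday multiplier
of 1.174, so the fitted effects recover the truth within estimation error.

The same analysis as a shell tool:

```
firegam run --seed 1 --level subregion --out results/demo
```

and as a narrative sequence: `analysis/01_simulate.py` …
`analysis/06_validate.py` (each writes its tables under `results/analysis/`).

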