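# ccteval

Impact evaluation and policy forecasting for conditional cash transfer
(CCT) programmes on municipal panel data.

CCT programmes such as Brazil's Bolsa Família transfer cash to poor
households conditional on health and education behaviours.  Their
population-level health effects are usually evaluated on ecological
panels — one record per municipality and year, with death and
hospitalisation counts, programme coverage, and socioeconomic
covariates.  `ccteval` implements that full evaluation pipeline for
epidemiologists and policy analysts:

1. **Synthetic panels** with known ground truth (`SimConfig`,
   `generate_panel`): staged programme roll-out, covariate drift,
   Poisson outcomes with configurable true rate ratios.
2. **Vital-statistics quality screening** (`VitalStatisticsFilter`): a
   multidimensional adequacy criterion (age-standardised mortality
   floor, birth-registration ratio, ill-defined-death share, composite
   deviation) that excludes municipalities with unreliable registries.
3. **Exposure coding** (`ExposureTransformer`): target coverage
   `C = 100·enrolled/eligible` (%) binned at [0,30)/[30,70)/[70,100)/[100,∞)
   into low/intermediate/high/consolidated; adequacy
   `A = transferred/enrolled` (BRL/family/month) binned at pooled
   quartiles; a 2×2 adequacy-by-coverage interaction; covariates
   dichotomised at their pooled median.
4. **Fixed-effects Poisson regression** (`FixedEffectsPoisson`):

   `y_mt ~ Poisson( d_mt · exp(α_m + β'x_mt) )`

   with a person-denominator offset, municipality intercepts eliminated
   by the conditional (profile) likelihood, calendar-year controls, and
   cluster-robust covariance (delete-one-cluster jackknife by default).
   Effects are reported as rate ratios `RR = e^β` with Wald 95% CIs.
5. **Averted burden** (`averted_events`): Monte Carlo difference between
   predicted events under observed exposure and under a no-programme
   counterfactual, propagating coefficient uncertainty.
6. **Scenario microsimulation** (`extrapolate_covariates`,
   `apply_scenario`, `project_outcomes`, `compare_scenarios`): stage 1
   continues municipal covariate trends to a horizon; stage 2 predicts
   outcomes under expansion / baseline / austerity coverage scenarios
   with paired coefficient draws, yielding scenario rate ratios and
   cumulative avoidable events.
7. **Triangulation** (`PropensityScoreMatcher`, `did_estimate`):
   difference-in-differences on log rates between two anchor years over
   propensity-score-matched low- versus higher-coverage municipalities.

Transformers and estimators follow scikit-learn conventions
(`fit`/`transform`, `get_params`, fitted attributes with a trailing
underscore) and compose with sklearn pipelines; module-level functions
are thin wrappers.

## Worked example

```python
import ccteval as cc
from ccteval.io import COVARIATE_COLUMNS

cfg = cc.SimConfig(n_municipalities=300, seed=7)   # true consolidated RR 0.824
panel, truth = cc.generate_panel(cfg)

expo = cc.ExposureTransformer().fit(panel)
data = cc.dichotomize_covariates(expo.transform(panel), COVARIATE_COLUMNS)

model = cc.FixedEffectsPoisson(covariates=tuple(COVARIATE_COLUMNS)).fit(data)
rr = model.rate_ratios()
print(rr[rr["term"].str.startswith("coverage_level")].round(3).to_string(index=False))

averted = cc.averted_events(data, model, n_iterations=10_000, seed=7)
print(averted)
```

prints

```
                        term    RR  ci_low  ci_high   p
coverage_level[intermediate] 0.926   0.904    0.949 0.0
        coverage_level[high] 0.896   0.873    0.919 0.0
coverage_level[consolidated] 0.829   0.807    0.852 0.0
AvertedEvents(point=202590.8, 95% PI [161996.2, 244604.7], n_iterations=10000)
```

The fitted dose-response rate ratios recover the generator's ground
truth (0.924 / 0.890 / 0.824): municipality-years at consolidated
coverage have a mortality rate about 17% below comparable low-coverage
years, and the model-implied counterfactual without the programme
attributes roughly 200 000 of this panel's deaths to higher rates that
enrolment prevented (the 95% interval reflects coefficient
uncertainty).

A `ccteval` command-line interface exposes the same stages
(`simulate`, `filter`, `fit`, `averted`, `forecast`, `did`,
`summarize`, `run`) driven by a YAML config; `ccteval run` executes the
whole pipeline and writes per-stage CSVs plus a manifest recording the
seed, iteration counts and every dropped-record count.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic data
generator and its defaults, numerical choices, and known limitations.
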