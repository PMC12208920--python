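# Methods

## Estimand and model

The package evaluates a municipal cash-transfer programme's effect on
all-cause mortality and hospitalisation rates with an ecological panel
design: municipalities observed annually, outcomes as event counts,
exposure as the programme's dose in that municipality-year.

The core model is a fixed-effects Poisson rate regression,

    y_mt ~ Poisson( d_mt · exp( α_m + β'x_mt ) ),

where `d_mt` is the person denominator (total population; livebirths for
the under-5 stratum), `α_m` a municipality intercept absorbing all
time-invariant confounding (geography, history, administrative
capacity), and `x_mt` contains

* exposure dose indicators — target coverage level
  (low [0,30), intermediate [30,70), high [70,100), consolidated [100,∞) percent
  of eligible families enrolled), or adequacy level (quartiles of
  BRL/family/month), or their 2×2 interaction; the lowest level is the
  reference;
* dichotomised socioeconomic/health-system covariates (poverty,
  illiteracy, Gini, urbanisation, water, sanitation, physicians, beds,
  other programme coverages, fertility), split at the pooled-panel
  median by default;
* calendar-year indicators (full set by default; a three-shock-period
  variant — 2008–09, 2013–14, 2015–16 — is available for sensitivity
  runs).

Identification rests on within-municipality variation: municipalities
that moved through the dose categories at different times, net of
common year effects.  `exp(β)` is a rate ratio (RR).

### Fixed effects by conditional likelihood

With a log link, profiling the `α_m` out of the Poisson likelihood
gives, per municipality, a multinomial term
`Σ_t y_mt log p_mt` with `p_mt = r_mt / Σ_t' r_mt'`,
`r_mt = d_mt exp(x_mt'β)`.  Its maximiser equals the joint MLE of the
explicit-dummy parameterisation (there is no incidental-parameter
problem in this model), but the design stays at a few dozen columns for
thousands of municipalities.  The test suite verifies agreement with a
statsmodels dummy-GLM fit to at least six significant digits, and an
analytically saturated 2×2 fixture returns its closed-form RR exactly.
Municipalities whose outcome is zero in every year carry no information
about β (their profile intercept diverges); they are dropped and
counted.

Optimisation is full Newton with step-halving on the profile
log-likelihood; convergence requires a relative log-likelihood change
below 1e-10 and a gradient below 1e-8 scaled by the total event count.
Collinearity is detected on the within-municipality-demeaned design by
pivoted QR and reported with the aliased column names, because profile
likelihood cannot identify regressors that are constant within every
municipality (a covariate whose dichotomised version flips in the same
year everywhere is the common practical case).

### Cluster-robust covariance

Outcome series are overdispersed and serially correlated within
municipalities, so inference uses scores summed per municipality.  The
default covariance is a one-step delete-one-cluster jackknife (CR3):
`β_{-g} − β ≈ (H − H_g)^{-1} s_g`, with the jackknife spread as the
covariance.  The plain CR1 sandwich is available but, with ~500
clusters and ~33 regressors, it understates replicate-to-replicate
variability by roughly the ratio of regressors to clusters; the
jackknife removes that bias (both facts are measured by the acceptance
suite's replicated calibration).  Wald CIs on the jackknife SEs cover a
true RR of 0.82 at close to — in our replications slightly below — the
nominal 95% under the generator's realistic staggered dose paths, which
is the documented finite-sample behaviour of cluster-robust Wald
intervals.

## Synthetic panel generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is demonstrated.

It emulates: log-normal municipal heterogeneity of baseline rates
(log-SD 0.3); covariates drifting linearly with Gaussian noise,
truncated to valid ranges, with start levels and drifts matched to the
published 2004 municipal means and their 15-year changes (poverty
23.1% falling ~1.0 pt/yr, adequacy 71.67 BRL growing ~12%/yr, coverage
ramping from ~50% of the target population at the 2004 start to a
plateau near 100% by ~2010); targeted roll-out (poorer municipalities
ramp faster — the confounding fixed effects must absorb); a secular
log-rate drift plus common shock-year terms; eligible families derived
as poverty rate × households so that target coverage is well defined;
and Poisson age-group counts whose group rates are normalised so the
overall expected count is exactly
`population/1000 · R · exp(α_m + γ_t + β'x)` with `β` the logs of the
configured true RRs (defaults: the published dose-response estimates,
0.924/0.890/0.824 for mortality, 0.884/0.857/0.789 for
hospitalisation).  The default baseline mortality rate is the published
7.57/1000; the published overall hospitalisation rate is internally
inconsistent with its own age-group rates, so the generator uses
30/1000 with group weights matching the published relative magnitudes.
A gamma-frailty multiplier (`frailty_shape`) adds overdispersion on
demand; default outcomes are pure Poisson because robust errors, not
the likelihood, are meant to absorb overdispersion.  Two deliberately
small covariate effects on the outcome (poverty +0.004/pt, physicians
−0.02/unit) act on the *continuous* covariates, so the default
conditions include the dichotomisation mis-specification a real
analysis faces.

It does **not** emulate: Brazil's municipal size distribution or
spatial autocorrelation, migration or demographic ageing,
within-municipality benefit heterogeneity, or reverse causation from
outcomes to programme placement.  Passing recovery tests therefore show
the pipeline is correct under its stated assumptions, not that those
assumptions hold in any particular registry.

All randomness flows from one root seed through named substreams
(structure, covariates, roll-out, outcomes), so panels are
bit-reproducible and outcome redraws do not disturb the covariate
paths.  `inject_quality_defects` degrades a labelled municipality
subset (deaths ×0.55, ill-defined share →25%, birth-registration ratio
→0.70) to exercise the quality screen.

## Quality screen

Municipalities are screened, never corrected, on four window-averaged
dimensions: an ASMR floor (default 4/1000 — implausibly low mortality
signals under-registration), a registered/estimated births floor
(default 0.90), an ill-defined-cause ceiling (default 10%), and a
composite ceiling on the mean adverse z-score of the previous three
(default 1.5).  The published criterion's numeric thresholds are not
printed in the sources this package reimplements, so these defaults
are explicit placeholders, configurable per run; correctness is
demonstrated against injected synthetic defects (≥90% detection at the
default magnitudes).  Tightening any threshold can only shrink the
passing set (verified property).

## Averted burden and microsimulation

Averted events compare predicted expected counts under observed
exposure with a counterfactual that resets exposure to the reference
category, holding municipality effects, denominators and covariates
fixed.  Parameter uncertainty is propagated by drawing coefficient
vectors from N(β̂, V̂) (cluster-robust V̂; Cholesky, with an eigenvalue
or diagonal fallback for singular V̂) and reported as 2.5–97.5
percentile intervals; Poisson sampling noise is deliberately excluded
because the estimand is the expected burden.  The Monte Carlo mean
matches the plug-in closed form to well under 1% at 10 000 iterations.

The microsimulation has two stages.  Stage 1 continues each
municipality's variables to the horizon (2024–2030 by default) with a
Theil–Sen slope over the last 10 observed years, clipping percentages
to [0,100] and counts to ≥0 (clips are counted and logged); an optional
Gaussian innovation makes it stochastic.  This deterministic trend
continuation is a simplification of full stochastic cohort modelling
that preserves municipal trends but not cross-variable correlation in
the innovations.  Stage 2 recomputes eligibility under the scenario's
poverty line (proportional multipliers, configurable: 1.6 for half the
minimum wage, 1.25 for a quarter — the true income-distribution mapping
is not published), sets coverage by scenario rule (expansion →100%;
baseline → each municipality's last observed coverage; austerity →
coverage × a constant annual reduction, default 0.92/yr, the published
factor not being printed), re-categorises exposure with the
estimation-period cut-points, and predicts outcomes with municipality
effects and the last fitted year effect carried forward.  Scenario
contrasts are *paired*: one coefficient draw feeds every scenario per
iteration, so a scenario compared with itself gives RR exactly 1 with a
zero-width interval, and the expansion-vs-baseline cumulative avoidable
events reproduce the closed form `Σ μ_B (1 − RR)` exactly at the point
estimate.

## Triangulation

The propensity for "beyond-low coverage at the first anchor year" is a
logistic model (statsmodels IRLS; coefficients above 15 in absolute
value raise a separation error).  Matching is greedy 1:1
nearest-neighbour on the linear propensity without replacement, caliper
0.2 SD of the linear propensity (standard practice), deterministic with
documented tie-breaks (treated processed in ascending id; ties to the
lower control id); a brute-force optimal matcher serves as the test
oracle.  The DiD is OLS of log(rate) on treated, post and their
interaction over the matched set, SE clustered on matched pair, on the
log scale so the exponentiated estimate is comparable with the Poisson
RRs.  Balance is reported as standardised mean differences before and
after matching.

## Problem sizes

The replicated calibration runs 200 replicates of 500 municipalities ×
20 years in the test suite (the calibration configuration switches the
two covariate outcome effects off so the data-generating process lies
inside the fitted model family; the mis-specified default conditions
are checked separately for bias) and 40 replicates in the acceptance
script; scenario projections use 1000 iterations and averted-burden
checks 10–20 thousand.  These sizes keep every Monte Carlo standard
error well inside the asserted tolerances.

## Known limitations

* Ecological design: effects are municipality-level associations;
  fixed effects and covariates cannot exclude time-varying confounding
  aligned with roll-out.
* The quality criterion's thresholds are placeholders (see above).
* Stage-1 projection ignores innovation correlation across variables
  and municipalities; horizon year effects are frozen at the last
  estimation year.
* The counterfactual holds programme-affected covariates (e.g.
  poverty) at observed values, so mediated effects through those
  covariates are not credited to the programme.
* Cluster-robust Wald intervals remain slightly anti-conservative in
  finite samples even with the jackknife covariance under strongly
  serially-dependent dose paths.
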