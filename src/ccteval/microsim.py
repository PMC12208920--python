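"""Two-stage policy-scenario microsimulation.

Stage 1 projects each municipality's covariates, population and
programme-eligibility inputs to a horizon (default 2024-2030) by
continuing municipal-specific trends (Theil-Sen slope over the last k
observed years), with percentages clipped to [0, 100] and counts to
nonnegative values.  This deterministic continuation is a simplification
of full stochastic cohort modelling and is documented as such.

Stage 2 feeds the projected panel, under named coverage scenarios, into
the fitted fixed-effects Poisson model: per Monte Carlo iteration a
coefficient vector is drawn (as in the averted-events module) and
expected events are predicted with municipality effects carried
unchanged from the estimation period.  Scenario contrasts are paired:
the same coefficient draw feeds the numerator and denominator of every
scenario rate ratio, so parameter uncertainty cancels where it should.

Scenarios
---------
* ``expansion`` — cover 100% of the (projected) eligible families:
  consolidated coverage everywhere.
* ``baseline`` — hold each municipality's last observed coverage.
* ``austerity`` — multiply coverage by a year-indexed reduction path
  (default: constant annual proportional decline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exposure import categorize_adequacy, categorize_coverage
from .fe_poisson import FixedEffectsPoisson

logger = logging.getLogger(__name__)

SCENARIO_NAMES = ("expansion", "baseline", "austerity")

#: eligibility inflation when the poverty line is raised (fraction of the
#: minimum wage); a raised line qualifies more families than the current
#: extreme-poverty threshold.  Configurable; not printed in any source.
ELIGIBILITY_MULTIPLIERS = {"current": 1.0,
                           "quarter_minimum_wage": 1.25,
                           "half_minimum_wage": 1.6}


@dataclass
class ScenarioSpec:
    """A named policy rule for the horizon years."""

    name: str
    poverty_line: str = "half_minimum_wage"
    coverage_rule: str | None = None        # defaults to the name
    annual_coverage_reduction: float = 0.92  # austerity only, in (0, 1]
    adequacy_rule: str = "hold"              # "hold" or "grow"
    adequacy_growth: float = 1.0

    def __post_init__(self):
        if self.coverage_rule is None:
            self.coverage_rule = self.name
        if self.coverage_rule not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario rule '{self.coverage_rule}'; "
                             f"expected one of {SCENARIO_NAMES}")
        if self.poverty_line not in ELIGIBILITY_MULTIPLIERS:
            raise ValueError(f"unknown poverty line '{self.poverty_line}'")
        if not 0 < self.annual_coverage_reduction <= 1:
            raise ValueError("annual_coverage_reduction must be in (0, 1]")


@dataclass
class Projection:
    """Iteration-matched expected events per scenario on the horizon."""

    years: np.ndarray
    population: np.ndarray                     # per horizon year
    events: dict                               # name -> (n_iter, n_years)
    point_events: dict                         # name -> (n_years,)
    n_iterations: int
    seed: int | None


@dataclass
class ScenarioComparison:
    scenario_a: str
    scenario_b: str
    per_year: pd.DataFrame      # year, rr, rr_low, rr_high
    avoidable: float            # cumulative events_b - events_a (point)
    avoidable_low: float
    avoidable_high: float
    n_iterations: int
    seed: int | None


PERCENT_COLUMNS = ("poverty_rate", "illiteracy_rate", "urbanization_rate",
                   "piped_water", "sanitation", "bpc_coverage", "esf_coverage")
COUNT_LIKE = ("population", "pop_under5", "pop_5_69", "pop_70plus",
              "livebirths", "estimated_births", "bfp_eligible")


class CovariateExtrapolator(BaseEstimator, TransformerMixin):
    """Deterministic per-municipality trend continuation.

    fit() learns a Theil-Sen (median-of-pairwise-slopes) line per
    municipality and variable on the last ``last_k`` observed years;
    transform(horizon_years) evaluates it, clipping to valid ranges.
    An optional Gaussian innovation can be added with a seed.
    """

    def __init__(self, variables=None, last_k=10, stochastic=False,
                 innovation_sd=0.0, seed=None):
        self.variables = variables
        self.last_k = last_k
        self.stochastic = stochastic
        self.innovation_sd = innovation_sd
        self.seed = seed

    def fit(self, panel: pd.DataFrame, y=None):
        variables = list(self.variables) if self.variables is not None else [
            c for c in panel.columns
            if c not in ("municipality", "year")
            and pd.api.types.is_numeric_dtype(panel[c])
            and not pd.api.types.is_bool_dtype(panel[c])]
        n_years = panel.groupby("municipality")["year"].nunique()
        if (n_years < 5).any():
            raise ValueError("every municipality needs >= 5 observed years "
                             "for trend extrapolation")
        lines = {}
        for m, g in panel.sort_values("year").groupby("municipality"):
            tail = g.tail(self.last_k)
            t = tail["year"].to_numpy(float)
            lines[m] = {}
            for v in variables:
                yv = tail[v].to_numpy(float)
                if np.all(np.isnan(yv)):
                    raise ValueError(
                        f"variable '{v}' is all-missing for municipality {m}")
                if np.allclose(yv, yv[0]):
                    slope, intercept = 0.0, yv[0]
                else:
                    slope, intercept, *_ = stats.theilslopes(yv, t)
                lines[m][v] = (slope, intercept)
        self.variables_ = variables
        self.lines_ = lines
        self.clip_log_: dict = {}
        return self

    def transform(self, horizon_years) -> pd.DataFrame:
        if not hasattr(self, "lines_"):
            raise RuntimeError("CovariateExtrapolator is not fitted")
        years = np.asarray(list(horizon_years), dtype=int)
        rng = np.random.default_rng(self.seed) if self.stochastic else None
        rows = []
        clip_counts: dict = {}
        for m, lv in self.lines_.items():
            for yr in years:
                row = {"municipality": m, "year": int(yr)}
                for v in self.variables_:
                    slope, intercept = lv[v]
                    val = intercept + slope * yr
                    if rng is not None and self.innovation_sd > 0:
                        val += rng.normal(0.0, self.innovation_sd)
                    lo = 0.0 if (v in PERCENT_COLUMNS or v in COUNT_LIKE
                                 or v.endswith("_per_1000")
                                 or v == "fertility_rate"
                                 or v == "gini") else -np.inf
                    hi = 100.0 if (v in PERCENT_COLUMNS or v == "gini") \
                        else np.inf
                    clipped = min(max(val, lo), hi)
                    if clipped != val:
                        clip_counts[v] = clip_counts.get(v, 0) + 1
                    if v in COUNT_LIKE:
                        clipped = float(np.rint(clipped))
                    row[v] = clipped
                rows.append(row)
        self.clip_log_ = clip_counts
        for v, n in clip_counts.items():
            logger.info("extrapolation clipped %d projected value(s) of %s",
                        n, v)
        return pd.DataFrame(rows)


def extrapolate_covariates(panel: pd.DataFrame, horizon_years,
                           variables=None, last_k=10, stochastic=False,
                           innovation_sd=0.0, seed=None) -> pd.DataFrame:
    """Stage-1 panel: trend-continued municipal variables on the horizon."""
    years = np.asarray(list(horizon_years), dtype=int)
    observed = set(panel["year"].unique())
    if observed & set(years.tolist()):
        raise ValueError("horizon years must be disjoint from observed years")
    ex = CovariateExtrapolator(variables=variables, last_k=last_k,
                               stochastic=stochastic,
                               innovation_sd=innovation_sd, seed=seed)
    return ex.fit(panel).transform(years)


def _last_observed(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-municipality last-year coverage and adequacy."""
    last = (panel.sort_values("year").groupby("municipality").tail(1)
            .set_index("municipality"))
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(last["bfp_eligible"] > 0,
                       100.0 * last["bfp_enrolled"] / last["bfp_eligible"], 0.0)
        adq = np.where(last["bfp_enrolled"] > 0,
                       last["bfp_transferred"] / last["bfp_enrolled"], 0.0)
    return pd.DataFrame({"last_coverage": cov, "last_adequacy": adq,
                         "last_year": last["year"]}, index=last.index)


def apply_scenario(stage1: pd.DataFrame, scenario: ScenarioSpec,
                   observed_panel: pd.DataFrame,
                   coverage_cuts=(30.0, 70.0, 100.0),
                   adequacy_cuts=(61.44, 99.13, 151.23)) -> pd.DataFrame:
    """Exposure trajectories for one scenario on the stage-1 panel.

    Eligible families are recomputed under the scenario's poverty line
    (proportional inflation of the projected eligible count); coverage
    and adequacy follow the scenario rule; categories are assigned with
    the estimation-period cut-points.
    """
    last = _last_observed(observed_panel)
    out = stage1.merge(last, left_on="municipality", right_index=True,
                       how="left")
    if out["last_coverage"].isna().any():
        missing = sorted(set(stage1["municipality"])
                         - set(last.index))[:5]
        raise ValueError(f"stage-1 municipalities unseen in the observed "
                         f"panel: {missing}")
    mult = ELIGIBILITY_MULTIPLIERS[scenario.poverty_line]
    if "bfp_eligible" in out.columns:
        out["bfp_eligible"] = np.maximum(
            1, np.rint(out["bfp_eligible"] * mult)).astype(int)

    rule = scenario.coverage_rule
    if rule == "expansion":
        coverage = np.full(len(out), 100.0)
    elif rule == "baseline":
        coverage = out["last_coverage"].to_numpy(float)
    else:  # austerity
        dt = (out["year"] - out["last_year"]).to_numpy(int)
        coverage = (out["last_coverage"].to_numpy(float)
                    * scenario.annual_coverage_reduction ** np.maximum(dt, 0))
    coverage = np.clip(coverage, 0.0, None)

    adequacy = out["last_adequacy"].to_numpy(float)
    if scenario.adequacy_rule == "grow":
        dt = (out["year"] - out["last_year"]).to_numpy(int)
        adequacy = adequacy * scenario.adequacy_growth ** np.maximum(dt, 0)

    out["target_coverage"] = coverage
    out["adequacy"] = adequacy
    out["coverage_level"] = categorize_coverage(coverage, coverage_cuts)
    out["adequacy_level"] = categorize_adequacy(adequacy, adequacy_cuts)
    out["scenario"] = scenario.name
    return out.drop(columns=["last_coverage", "last_adequacy", "last_year"])


def project_outcomes(trajectories: dict, model: FixedEffectsPoisson,
                     n_iterations: int = 10_000, seed: int | None = None
                     ) -> Projection:
    """Stage 2: iteration-matched expected events per scenario.

    ``trajectories`` maps scenario name -> stage-1 panel with exposure
    columns (from :func:`apply_scenario`) and the model's covariate
    columns already dichotomised with the estimation-period thresholds.
    One common set of coefficient draws feeds every scenario (paired).
    """
    from .counterfactual import _coef_sampler

    names = list(trajectories)
    first = trajectories[names[0]]
    years = np.sort(first["year"].unique())
    designs = {}
    for name in names:
        df = trajectories[name]
        if not np.array_equal(np.sort(df["year"].unique()), years):
            raise ValueError("scenario trajectories cover different years")
        X, base = model.design_for(df)
        keep = np.isfinite(base)
        yr = df["year"].to_numpy()[keep]
        designs[name] = (X[keep], base[keep], yr)

    pop = (first.groupby("year")["population"].sum()
           .reindex(years).to_numpy(float)
           if "population" in first.columns else np.ones(len(years)))

    coef = model.coef_.to_numpy()
    year_codes = {name: np.searchsorted(years, yr)
                  for name, (_, _, yr) in designs.items()}
    point_events = {}
    for name, (X, base, yr) in designs.items():
        mu = np.exp(base + X @ coef)
        point_events[name] = np.bincount(year_codes[name], weights=mu,
                                         minlength=len(years))

    rng = np.random.default_rng(seed)
    sampler = _coef_sampler(model)
    events = {name: np.empty((n_iterations, len(years))) for name in names}
    done = 0
    while done < n_iterations:
        n = min(256, n_iterations - done)
        B = sampler(rng, n)                                  # (n, k)
        for name, (X, base, yr) in designs.items():
            mu = np.exp(base[:, None] + X @ B.T)             # (rows, n)
            codes = year_codes[name]
            agg = np.zeros((n, len(years)))
            for j in range(len(years)):
                agg[:, j] = mu[codes == j].sum(axis=0)
            events[name][done:done + n] = agg
        done += n
    return Projection(years=years, population=pop, events=events,
                      point_events=point_events, n_iterations=n_iterations,
                      seed=seed)


def compare_scenarios(projection: Projection, scenario_a: str,
                      scenario_b: str) -> ScenarioComparison:
    """Paired per-year rate ratios A/B and cumulative avoidable events
    (events under B minus under A), with percentile intervals."""
    for s in (scenario_a, scenario_b):
        if s not in projection.events:
            raise ValueError(f"scenario '{s}' not in the projection")
    ev_a, ev_b = projection.events[scenario_a], projection.events[scenario_b]
    if ev_a.shape != ev_b.shape:
        raise ValueError("unmatched iteration counts between scenarios")
    pt_a = projection.point_events[scenario_a]
    pt_b = projection.point_events[scenario_b]

    with np.errstate(divide="ignore", invalid="ignore"):
        rr_draws = ev_a / ev_b
        rr_point = pt_a / pt_b
    rr_lo, rr_hi = np.percentile(rr_draws, [2.5, 97.5], axis=0)
    per_year = pd.DataFrame({"year": projection.years, "rr": rr_point,
                             "rr_low": rr_lo, "rr_high": rr_hi})
    avoid_draws = (ev_b - ev_a).sum(axis=1)
    lo, hi = np.percentile(avoid_draws, [2.5, 97.5])
    return ScenarioComparison(
        scenario_a=scenario_a, scenario_b=scenario_b, per_year=per_year,
        avoidable=float((pt_b - pt_a).sum()),
        avoidable_low=float(lo), avoidable_high=float(hi),
        n_iterations=projection.n_iterations, seed=projection.seed)
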