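"""Synthetic municipal panel generator.

Emulates the statistical structure the evaluation pipeline assumes: a
long panel of municipality-years with

* log-normal heterogeneity of municipal baseline mortality and
  hospitalisation rates,
* secular linear drift (plus noise) of socioeconomic covariates,
* a staged cash-transfer roll-out in which target coverage ramps from
  ~50% of the target population at programme start to a plateau near
  100%, faster in poorer municipalities (targeted roll-out, which is the
  confounding that municipality fixed effects must absorb),
* per-family transfer adequacy growing multiplicatively, and
* Poisson-distributed age-group outcome counts whose log rates respond
  to the coverage (and optionally adequacy) dose categories with
  configurable ground-truth rate ratios.

The expected count of record *(m, t)* for the overall outcome is

    population(m,t)/1000 * R * exp(alpha_m + gamma_t + sum_k beta_k x_k)

where ``R`` is the configured baseline rate per 1000, ``alpha_m`` the
municipal deviation, ``gamma_t`` a secular drift plus shock-year terms
and ``beta`` the logs of the configured true rate ratios.  Age-group
counts are drawn from group-level rates normalised so their expectations
sum exactly to the overall expectation, which is stored as ground truth.

All randomness flows from a single root seed through named substreams
(structure, covariates, rollout, outcomes) so that, e.g., redrawing
outcomes does not perturb the covariate paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import (DEFAULT_COVERAGE_CUTS, REFERENCE_ADEQUACY_CUTS,
                       categorize_adequacy, categorize_coverage)

# -- study-condition defaults -------------------------------------------------

#: ground-truth mortality rate ratios by coverage dose level
DEFAULT_RR_MORTALITY = {"low": 1.0, "intermediate": 0.924,
                        "high": 0.890, "consolidated": 0.824}
#: ground-truth hospitalisation rate ratios by coverage dose level
DEFAULT_RR_HOSPITALISATION = {"low": 1.0, "intermediate": 0.884,
                              "high": 0.857, "consolidated": 0.789}

#: covariate trajectories: (start mean, start SD across municipalities,
#: annual drift, year-to-year noise SD, lower bound, upper bound)
DEFAULT_COVARIATE_TRENDS = {
    "poverty_rate":        (23.07, 10.0, -1.04, 0.80, 0.0, 100.0),
    "illiteracy_rate":     (10.89,  5.0, -0.41, 0.30, 0.0, 100.0),
    "gini":                (56.70,  5.0, -0.28, 0.60, 0.0, 100.0),
    "urbanization_rate":   (86.71,  8.0,  0.26, 0.40, 0.0, 100.0),
    "piped_water":         (80.39, 10.0,  0.47, 0.80, 0.0, 100.0),
    "sanitation":          (11.97,  8.0,  1.02, 0.80, 0.0, 100.0),
    "physicians_per_1000": (1.41,   0.5,  0.05, 0.04, 0.0, 50.0),
    "beds_per_1000":       (2.93,   1.0, -0.046, 0.06, 0.0, 50.0),
    "bpc_coverage":        (1.02,   0.4,  0.081, 0.05, 0.0, 100.0),
    "esf_coverage":        (13.01, 10.0,  3.12, 1.50, 0.0, 100.0),
    "fertility_rate":      (3.33,   0.4, -0.052, 0.03, 0.5, 10.0),
}

#: modest log-linear covariate effects on both outcome rates,
#: per unit of the (continuous) covariate relative to its start level
DEFAULT_COVARIATE_LOG_EFFECTS = {"poverty_rate": 0.004,
                                 "physicians_per_1000": -0.02}

AGE_SHARES = {"under5": 0.09, "5_69": 0.84, "70plus": 0.07}
LIVEBIRTH_RATE = 15.0          # livebirths per 1000 population per year

#: relative age-group rate levels (per 1000 of the group denominator),
#: normalised at runtime so the overall expectation is exact
MORTALITY_GROUP_WEIGHTS = {"under5": 24.32, "5_69": 3.84, "70plus": 68.03}
HOSP_GROUP_WEIGHTS = {"under5": 799.30, "5_69": 4.12, "70plus": 185.30}


@dataclass
class RolloutSpec:
    """Per-municipality coverage trajectory parameters.

    Coverage is 0 before ``start_year``, jumps to a municipality-specific
    start level, ramps linearly to a plateau over a municipality-specific
    number of years, then stays flat.  ``targeting`` scales how much
    faster poorer municipalities reach the plateau (roll-out priority).
    """

    start_year: int = 2004
    start_coverage_mean: float = 50.0
    start_coverage_sd: float = 15.0
    plateau_mean: float = 100.0
    plateau_sd: float = 3.0
    ramp_years_mean: float = 6.0
    ramp_years_sd: float = 2.0
    targeting: float = 1.0


@dataclass
class SimConfig:
    """Full parameterisation of one synthetic panel."""

    n_municipalities: int = 100
    year_start: int = 2000
    year_end: int = 2019
    seed: int = 0
    true_rr_mortality: dict = field(
        default_factory=lambda: dict(DEFAULT_RR_MORTALITY))
    true_rr_hospitalisation: dict = field(
        default_factory=lambda: dict(DEFAULT_RR_HOSPITALISATION))
    true_rr_adequacy: dict | None = None     # optional adequacy-dose effect
    true_rr_by_age_group: dict | None = None  # e.g. {"under5": {...}} override
    baseline_mortality_per_1000: float = 7.57
    baseline_hosp_per_1000: float = 30.0
    baseline_rate_log_sd: float = 0.3
    covariate_trend_spec: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_TRENDS))
    covariate_log_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOG_EFFECTS))
    rollout_spec: RolloutSpec = field(default_factory=RolloutSpec)
    adequacy_start: float = 71.67
    adequacy_growth: float = 1.12
    population_range: tuple = (2_000, 200_000)
    population_growth: float = 0.005
    year_log_drift: float = -0.005
    time_shock_years: tuple = (2008, 2009, 2013, 2014, 2015, 2016)
    time_shock_log: float = 0.02
    frailty_shape: float | None = None       # gamma overdispersion switch
    coverage_cuts: tuple = DEFAULT_COVERAGE_CUTS
    adequacy_cuts: tuple = REFERENCE_ADEQUACY_CUTS

    def validate(self) -> None:
        if self.n_municipalities < 1:
            raise ValueError("n_municipalities must be a positive integer")
        if self.year_end <= self.year_start:
            raise ValueError("years must span at least 2 distinct values "
                             "(year_end > year_start)")
        lo, hi = self.population_range
        if lo < 1 or hi < lo:
            raise ValueError("population_range min must be >= 1 and <= max")
        for name in ("true_rr_mortality", "true_rr_hospitalisation"):
            for lvl, rr in getattr(self, name).items():
                if rr <= 0:
                    raise ValueError(f"{name}[{lvl!r}] must be > 0")
        if self.true_rr_adequacy is not None:
            for lvl, rr in self.true_rr_adequacy.items():
                if rr <= 0:
                    raise ValueError(f"true_rr_adequacy[{lvl!r}] must be > 0")
        if self.baseline_rate_log_sd < 0:
            raise ValueError("baseline_rate_log_sd must be nonnegative")
        if self.baseline_mortality_per_1000 <= 0:
            raise ValueError("baseline_mortality_per_1000 must be > 0")
        if self.baseline_hosp_per_1000 <= 0:
            raise ValueError("baseline_hosp_per_1000 must be > 0")
        if self.adequacy_growth <= 0:
            raise ValueError("adequacy_growth must be > 0")
        if self.frailty_shape is not None and self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be > 0 when set")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``records`` holds, per municipality-year, the true expected overall
    counts and the exposure categories in force; ``baseline_log_rates``
    the municipal deviations alpha_m of the mortality model.
    """

    records: pd.DataFrame
    baseline_log_rates: pd.Series
    config: SimConfig


def _streams(seed: int) -> dict:
    root = np.random.SeedSequence(seed)
    names = ("structure", "covariates", "rollout", "outcomes")
    return {n: np.random.default_rng(s)
            for n, s in zip(names, root.spawn(len(names)))}


def _normalized_group_rates(overall_rate: float, weights: dict) -> dict:
    """Scale raw group rate levels so group expectations sum to the
    overall expectation: sum_g denomfrac_g * rate_g = overall_rate."""
    denomfrac = {"under5": LIVEBIRTH_RATE / 1000.0,
                 "5_69": AGE_SHARES["5_69"],
                 "70plus": AGE_SHARES["70plus"]}
    total = sum(denomfrac[g] * weights[g] for g in weights)
    c = overall_rate / total
    return {g: c * weights[g] for g in weights}


def generate_panel(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one panel plus its ground truth.  Bit-reproducible."""
    config.validate()
    rng = _streams(config.seed)
    M, years = config.n_municipalities, config.years
    T = len(years)
    ids = np.array([f"M{i:05d}" for i in range(1, M + 1)])

    # -- municipal structure ------------------------------------------------
    g = rng["structure"]
    lo, hi = config.population_range
    pop0 = np.exp(g.uniform(np.log(lo), np.log(hi), M))
    u = g.normal(size=M)                       # shared latent: deprivation
    e_mort = g.normal(size=M)
    e_hosp = g.normal(size=M)
    alpha_mort = config.baseline_rate_log_sd * (0.6 * u + 0.8 * e_mort)
    alpha_hosp = config.baseline_rate_log_sd * (0.6 * u + 0.8 * e_hosp)

    # -- covariate paths ----------------------------------------------------
    gc = rng["covariates"]
    cov_paths: dict[str, np.ndarray] = {}       # name -> (M, T)
    t_idx = np.arange(T)
    for name, spec in config.covariate_trend_spec.items():
        start, start_sd, drift, noise_sd, clip_lo, clip_hi = spec
        if name == "poverty_rate":
            # poverty start correlated with the deprivation latent
            start_m = start + start_sd * (0.6 * u + 0.8 * gc.normal(size=M))
        else:
            start_m = start + start_sd * gc.normal(size=M)
        noise = gc.normal(scale=noise_sd, size=(M, T))
        path = start_m[:, None] + drift * t_idx[None, :] + noise
        cov_paths[name] = np.clip(path, clip_lo, clip_hi)

    # -- roll-out: coverage trajectories ------------------------------------
    gr = rng["rollout"]
    rs = config.rollout_spec
    pov_start = cov_paths.get("poverty_rate", np.zeros((M, T)))[:, 0]
    pov_z = ((pov_start - pov_start.mean()) / pov_start.std()
             if pov_start.std() > 0 else np.zeros(M))
    start_cov = np.clip(
        gr.normal(rs.start_coverage_mean, rs.start_coverage_sd, M), 0, None)
    plateau = np.clip(gr.normal(rs.plateau_mean, rs.plateau_sd, M), 0, None)
    ramp = np.clip(gr.normal(rs.ramp_years_mean, rs.ramp_years_sd, M)
                   - rs.targeting * pov_z, 1.0, None)
    cov_path = np.zeros((M, T))
    for j, yr in enumerate(years):
        dt = yr - rs.start_year
        if dt < 0:
            continue
        frac = np.clip(dt / ramp, 0.0, 1.0)
        cov_path[:, j] = start_cov + frac * (plateau - start_cov)
    # monotone non-decreasing until plateau by construction (linear ramp)

    adequacy_start_m = config.adequacy_start * np.exp(0.1 * gr.normal(size=M))
    adq_path = np.zeros((M, T))
    for j, yr in enumerate(years):
        dt = yr - rs.start_year
        if dt >= 0:
            adq_path[:, j] = adequacy_start_m * config.adequacy_growth ** dt

    # -- assemble long panel -------------------------------------------------
    go = rng["outcomes"]
    growth = (1.0 + config.population_growth) ** t_idx
    pop = np.rint(pop0[:, None] * growth[None, :])
    fert = cov_paths.get("fertility_rate")
    fert_ratio = (fert / fert[:, :1]) if fert is not None else np.ones((M, T))
    livebirths = np.rint(pop * (LIVEBIRTH_RATE / 1000.0) * fert_ratio)
    households = pop / 3.3
    poverty = cov_paths.get("poverty_rate", np.full((M, T), 20.0))
    eligible = np.maximum(1, np.rint(poverty / 100.0 * households))
    enrolled = np.rint(cov_path / 100.0 * eligible)
    coverage = 100.0 * enrolled / eligible
    transferred = adq_path * enrolled
    adequacy = np.where(enrolled > 0, transferred / np.maximum(enrolled, 1), 0.0)

    cov_level = categorize_coverage(coverage.ravel(), config.coverage_cuts)
    log_rr_mort = np.log([config.true_rr_mortality[l] for l in
                          cov_level.categories])[cov_level.codes]
    log_rr_hosp = np.log([config.true_rr_hospitalisation[l] for l in
                          cov_level.categories])[cov_level.codes]
    if config.true_rr_adequacy is not None:
        adq_level = categorize_adequacy(adequacy.ravel(), config.adequacy_cuts)
        extra = np.log([config.true_rr_adequacy[l] for l in
                        adq_level.categories])[adq_level.codes]
        log_rr_mort = log_rr_mort + extra
        log_rr_hosp = log_rr_hosp + extra

    gamma = config.year_log_drift * t_idx + np.isin(
        years, np.asarray(config.time_shock_years)) * config.time_shock_log
    cov_lp = np.zeros((M, T))
    for name, eff in config.covariate_log_effects.items():
        if eff == 0 or name not in cov_paths:
            continue
        start = config.covariate_trend_spec[name][0]
        cov_lp += eff * (cov_paths[name] - start)

    lp_shared = (gamma[None, :] + cov_lp).ravel()
    lp_mort = alpha_mort[:, None].repeat(T, 1).ravel() + lp_shared + log_rr_mort
    lp_hosp = alpha_hosp[:, None].repeat(T, 1).ravel() + lp_shared + log_rr_hosp

    denom = {"under5": livebirths.ravel(),
             "5_69": np.rint(AGE_SHARES["5_69"] * pop).ravel(),
             "70plus": np.rint(AGE_SHARES["70plus"] * pop).ravel()}
    pop_flat = pop.ravel()

    def _draw_counts(overall_rate, weights, lp, rr_by_group):
        rates = _normalized_group_rates(overall_rate, weights)
        counts, expected_total = {}, np.zeros(M * T)
        for grp in rates:
            mu = denom[grp] / 1000.0 * rates[grp] * np.exp(lp)
            if rr_by_group and grp in rr_by_group:
                codes = cov_level.codes
                grp_log = np.log([rr_by_group[grp][l]
                                  for l in cov_level.categories])[codes]
                mu = denom[grp] / 1000.0 * rates[grp] * np.exp(
                    lp - (log_rr_mort if weights is MORTALITY_GROUP_WEIGHTS
                          else log_rr_hosp) + grp_log)
            expected_total += mu
            mean = mu
            if config.frailty_shape is not None:
                k = config.frailty_shape
                mean = mu * go.gamma(shape=k, scale=1.0 / k, size=mu.shape)
            counts[grp] = go.poisson(mean)
        return counts, expected_total

    rr_grp = config.true_rr_by_age_group
    d_counts, d_expected = _draw_counts(
        config.baseline_mortality_per_1000, MORTALITY_GROUP_WEIGHTS,
        lp_mort, rr_grp)
    h_counts, h_expected = _draw_counts(
        config.baseline_hosp_per_1000, HOSP_GROUP_WEIGHTS, lp_hosp, None)

    deaths_total = sum(d_counts.values())
    ill_frac = go.uniform(0.01, 0.06, M)
    ill_defined = go.binomial(deaths_total.astype(int),
                              ill_frac[:, None].repeat(T, 1).ravel())
    reg_ratio = np.clip(go.normal(1.0, 0.03, M), 0.9, 1.1)
    estimated_births = np.rint(
        livebirths.ravel() / reg_ratio[:, None].repeat(T, 1).ravel())

    panel = pd.DataFrame({
        "municipality": np.repeat(ids, T),
        "year": np.tile(years, M),
        "population": pop_flat.astype(int),
        "pop_under5": np.rint(AGE_SHARES["under5"] * pop_flat).astype(int),
        "pop_5_69": denom["5_69"].astype(int),
        "pop_70plus": denom["70plus"].astype(int),
        "livebirths": denom["under5"].astype(int),
        "estimated_births": estimated_births.astype(int),
        "deaths": deaths_total.astype(int),
        "deaths_under5": d_counts["under5"].astype(int),
        "deaths_5_69": d_counts["5_69"].astype(int),
        "deaths_70plus": d_counts["70plus"].astype(int),
        "ill_defined_deaths": ill_defined.astype(int),
        "hospitalisations": sum(h_counts.values()).astype(int),
        "hosp_under5": h_counts["under5"].astype(int),
        "hosp_5_69": h_counts["5_69"].astype(int),
        "hosp_70plus": h_counts["70plus"].astype(int),
        "bfp_enrolled": enrolled.ravel().astype(int),
        "bfp_eligible": eligible.ravel().astype(int),
        "bfp_transferred": transferred.ravel(),
    })
    for name, path in cov_paths.items():
        panel[name] = path.ravel()

    truth = GroundTruth(
        records=pd.DataFrame({
            "municipality": panel["municipality"],
            "year": panel["year"],
            "expected_deaths": d_expected,
            "expected_hospitalisations": h_expected,
            "coverage_level": np.asarray(cov_level),
            "planned_coverage": cov_path.ravel(),
        }),
        baseline_log_rates=pd.Series(alpha_mort, index=ids,
                                     name="alpha_mortality"),
        config=config)
    return panel, truth


def inject_quality_defects(panel: pd.DataFrame, fraction: float, seed: int
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Degrade vital statistics in a labelled subset of municipalities.

    The defect emulates under-registration: death counts downscaled,
    ill-defined-cause share inflated, and the registered/estimated birth
    ratio depressed.  Exactly ``round(fraction * M)`` municipalities are
    affected; their ids are returned for test assertions.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    ids = np.sort(panel["municipality"].unique())
    n_def = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    defective = np.sort(rng.choice(ids, size=n_def, replace=False))
    if n_def == 0:
        return panel.copy(), defective

    out = panel.copy()
    mask = out["municipality"].isin(defective).to_numpy()
    for col in ("deaths", "deaths_under5", "deaths_5_69", "deaths_70plus"):
        out.loc[mask, col] = np.floor(out.loc[mask, col] * 0.55).astype(int)
    out.loc[mask, "ill_defined_deaths"] = np.rint(
        out.loc[mask, "deaths"] * 0.25).astype(int)
    out.loc[mask, "estimated_births"] = np.rint(
        out.loc[mask, "livebirths"] / 0.70).astype(int)
    return out, defective
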