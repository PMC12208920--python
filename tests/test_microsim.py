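import numpy as np
import pandas as pd
import pytest

import ccteval as cc
from ccteval.microsim import Projection, _last_observed


@pytest.fixture(scope="module")
def fitted_small():
    cfg = cc.SimConfig(n_municipalities=60, seed=31, covariate_log_effects={})
    panel, _ = cc.generate_panel(cfg)
    expo = cc.ExposureTransformer().fit(panel)
    p2 = expo.transform(panel)
    m = cc.FixedEffectsPoisson(covariates=()).fit(p2)
    return p2, expo, m


def _toy_series(values_by_year):
    rows = []
    for yr, v in values_by_year.items():
        rows.append({"municipality": "A", "year": yr, "v": v})
    return pd.DataFrame(rows)


def test_constant_variable_projects_constant():
    df = _toy_series({y: 4.2 for y in range(2000, 2010)})
    out = cc.extrapolate_covariates(df, [2024, 2025], variables=["v"])
    assert np.allclose(out["v"], 4.2)


def test_exact_linear_trend_extrapolates_exactly():
    # v = 2 + 0.5*(year-2000) observed 2000-2023 -> 17.0 at 2030
    df = _toy_series({y: 2 + 0.5 * (y - 2000) for y in range(2000, 2024)})
    out = cc.extrapolate_covariates(df, [2030], variables=["v"])
    assert out["v"].iloc[0] == pytest.approx(17.0)


def test_negative_trend_clipped_with_log():
    df = _toy_series({y: 10 - 2.0 * (y - 2000) for y in range(2000, 2010)})
    df = df.rename(columns={"v": "poverty_rate"})
    ex = cc.CovariateExtrapolator(variables=["poverty_rate"]).fit(df)
    out = ex.transform([2024, 2025])
    assert (out["poverty_rate"] == 0.0).all()
    assert ex.clip_log_["poverty_rate"] == 2


def test_extrapolation_preconditions():
    df = _toy_series({2000: 1.0, 2001: 2.0})
    with pytest.raises(ValueError, match=">= 5"):
        cc.extrapolate_covariates(df, [2024], variables=["v"])
    long = _toy_series({y: 1.0 for y in range(2000, 2010)})
    with pytest.raises(ValueError, match="disjoint"):
        cc.extrapolate_covariates(long, [2005], variables=["v"])


def test_scenario_rules(fitted_small):
    p2, expo, m = fitted_small
    stage1 = cc.extrapolate_covariates(p2, range(2024, 2027))
    last = _last_observed(p2)
    for name in ("expansion", "baseline", "austerity"):
        traj = cc.apply_scenario(stage1, cc.ScenarioSpec(name=name), p2,
                                 adequacy_cuts=expo.adequacy_cuts_)
        if name == "expansion":
            assert (np.asarray(traj["coverage_level"]) == "consolidated").all()
        elif name == "baseline":
            merged = traj.merge(last, left_on="municipality",
                                right_index=True)
            assert merged["target_coverage"].to_numpy() == pytest.approx(
                merged["last_coverage"].to_numpy())
        else:
            spec = cc.ScenarioSpec(name="austerity")
            merged = traj.merge(last, left_on="municipality",
                                right_index=True)
            dt = merged["year"] - merged["last_year"]
            expect = merged["last_coverage"] \
                * spec.annual_coverage_reduction ** dt
            assert merged["target_coverage"].to_numpy() == pytest.approx(
                expect.to_numpy())


def test_austerity_arithmetic_recategorises():
    spec = cc.ScenarioSpec(name="austerity", annual_coverage_reduction=0.8)
    assert 99.0 * 0.8 == pytest.approx(79.2)
    assert cc.categorize_coverage(79.2) == "high"


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError, match="unknown scenario"):
        cc.ScenarioSpec(name="collapse_everything")


def test_identical_scenarios_identical_projection(fitted_small):
    p2, expo, m = fitted_small
    stage1 = cc.extrapolate_covariates(p2, range(2024, 2027))
    t1 = cc.apply_scenario(stage1, cc.ScenarioSpec(name="baseline"), p2,
                           adequacy_cuts=expo.adequacy_cuts_)
    proj = cc.project_outcomes({"a": t1, "b": t1.copy()}, m,
                               n_iterations=150, seed=5)
    comp = cc.compare_scenarios(proj, "a", "b")
    assert (comp.per_year["rr"] == 1.0).all()
    assert (comp.per_year["rr_low"] == 1.0).all()
    assert (comp.per_year["rr_high"] == 1.0).all()
    assert comp.avoidable == 0.0
    assert comp.avoidable_low == comp.avoidable_high == 0.0


def test_population_doubling_doubles_events_not_rates(fitted_small):
    p2, expo, m = fitted_small
    stage1 = cc.extrapolate_covariates(p2, range(2024, 2026))
    traj = cc.apply_scenario(stage1, cc.ScenarioSpec(name="expansion"), p2,
                             adequacy_cuts=expo.adequacy_cuts_)
    doubled = traj.assign(population=traj["population"] * 2)
    proj = cc.project_outcomes({"x1": traj, "x2": doubled}, m,
                               n_iterations=50, seed=9)
    assert proj.point_events["x2"] == pytest.approx(
        2 * proj.point_events["x1"], rel=1e-9)


def test_arithmetic_comparison_fixture():
    """A projected 920 vs 1000 events per year at every iteration gives
    RR 0.92 and 80 * n_years avoidable."""
    years = np.arange(2024, 2031)
    ev_a = np.full((200, len(years)), 920.0)
    ev_b = np.full((200, len(years)), 1000.0)
    proj = Projection(years=years, population=np.ones(len(years)),
                      events={"a": ev_a, "b": ev_b},
                      point_events={"a": ev_a[0], "b": ev_b[0]},
                      n_iterations=200, seed=0)
    comp = cc.compare_scenarios(proj, "a", "b")
    assert np.allclose(comp.per_year["rr"], 0.92)
    assert comp.avoidable == pytest.approx(80.0 * len(years))


def test_pairing_tightens_intervals(fitted_small):
    """Breaking the iteration pairing between two correlated scenario
    draws widens the RR interval."""
    p2, expo, m = fitted_small
    stage1 = cc.extrapolate_covariates(p2, range(2024, 2026))
    t_exp = cc.apply_scenario(stage1, cc.ScenarioSpec(name="expansion"), p2,
                              adequacy_cuts=expo.adequacy_cuts_)
    t_aus = cc.apply_scenario(
        stage1, cc.ScenarioSpec(name="austerity",
                                annual_coverage_reduction=0.6), p2,
        adequacy_cuts=expo.adequacy_cuts_)
    proj = cc.project_outcomes({"e": t_exp, "a": t_aus}, m,
                               n_iterations=400, seed=13)
    paired = cc.compare_scenarios(proj, "e", "a")
    rng = np.random.default_rng(0)
    shuffled = Projection(
        years=proj.years, population=proj.population,
        events={"e": proj.events["e"],
                "a": rng.permutation(proj.events["a"], axis=0)},
        point_events=proj.point_events,
        n_iterations=proj.n_iterations, seed=proj.seed)
    broken = cc.compare_scenarios(shuffled, "e", "a")
    width_p = (paired.per_year["rr_high"] - paired.per_year["rr_low"]).mean()
    width_b = (broken.per_year["rr_high"] - broken.per_year["rr_low"]).mean()
    assert width_p < width_b


def test_unmatched_iteration_counts_rejected():
    years = np.arange(2024, 2026)
    proj = Projection(years=years, population=np.ones(2),
                      events={"a": np.ones((100, 2)),
                              "b": np.ones((50, 2))},
                      point_events={"a": np.ones(2), "b": np.ones(2)},
                      n_iterations=100, seed=0)
    with pytest.raises(ValueError, match="unmatched iteration"):
        cc.compare_scenarios(proj, "a", "b")


def test_scenario_level_outside_fitted_design_rejected():
    """A fit that never saw consolidated coverage cannot project it."""
    df_rows = []
    rng = np.random.default_rng(2)
    for m_i in range(20):
        for t in range(10):
            df_rows.append({
                "municipality": f"M{m_i}", "year": 2000 + t,
                "deaths": int(rng.poisson(50)), "population": 10_000,
                "coverage_level": "low" if t < 3 + m_i % 5
                else "intermediate"})
    df = pd.DataFrame(df_rows)
    m = cc.FixedEffectsPoisson(covariates=()).fit(df)
    horizon = df[df["year"] == 2009].assign(year=2024,
                                            coverage_level="consolidated")
    with pytest.raises(ValueError, match="outside the fitted design"):
        cc.project_outcomes({"x": horizon}, m, n_iterations=10, seed=1)
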