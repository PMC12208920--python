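import numpy as np
import pandas as pd
import pytest

import ccteval as cc
from ccteval.fe_poisson import fit_with_dummies
from ccteval.io import COVARIATE_COLUMNS


def _pure_panel(seed, M=60, T=8, rr=0.82, trend=-0.01):
    """Exactly-specified staggered-switch FE Poisson data."""
    rng = np.random.default_rng(seed)
    alpha = rng.normal(0, 0.3, M)
    pop = rng.integers(5000, 80000, M)
    switch = rng.integers(2, T - 1, M)
    years = np.arange(T)
    rows = []
    for m in range(M):
        x = (years >= switch[m]).astype(float)
        mu = pop[m] / 1000 * 7.5 * np.exp(alpha[m] + trend * years
                                          + np.log(rr) * x)
        y = rng.poisson(mu)
        for t in range(T):
            rows.append((f"M{m:03d}", 2000 + t, int(y[t]), int(pop[m]), x[t]))
    return pd.DataFrame(rows, columns=["municipality", "year", "deaths",
                                       "population", "x"])


def test_saturated_two_by_two_rr_exact(two_by_two):
    m = cc.FixedEffectsPoisson(exposure="exposed").fit(two_by_two)
    assert np.exp(m.coef_["exposed"]) == pytest.approx(0.8, abs=1e-9)


def test_conditional_equals_dummy_absorption():
    """The profile conditional likelihood and an explicit
    municipality-dummy GLM agree to at least 6 significant digits."""
    df = _pure_panel(seed=3, M=5, T=6)
    m = cc.FixedEffectsPoisson(exposure="x").fit(df)
    dummy = fit_with_dummies(df, m)
    for term in m.terms_:
        assert m.coef_[term] == pytest.approx(dummy[term], rel=1e-6, abs=1e-9)


def test_rate_ratio_table():
    df = _pure_panel(seed=4, M=40, T=8)
    m = cc.FixedEffectsPoisson(exposure="x").fit(df)
    rr = m.rate_ratios().set_index("term")
    assert ((rr["ci_low"] < rr["RR"]) & (rr["RR"] < rr["ci_high"])).all()
    # hand-checked Wald interval: exp(log .8 +- 1.96 * .05)
    m.coef_["x"] = np.log(0.8)
    m.cov_.loc["x", "x"] = 0.05 ** 2
    row = m.rate_ratios().set_index("term").loc["x"]
    assert row["RR"] == pytest.approx(0.8)
    from scipy import stats as st
    z = st.norm.ppf(0.975)
    assert row["ci_low"] == pytest.approx(0.8 * np.exp(-z * 0.05), abs=1e-12)
    assert row["ci_high"] == pytest.approx(0.8 * np.exp(z * 0.05), abs=1e-12)
    assert round(row["ci_low"], 3) == 0.725 and round(row["ci_high"], 3) == 0.882


def test_offset_scale_invariance():
    df = _pure_panel(seed=5, M=30, T=6)
    m1 = cc.FixedEffectsPoisson(exposure="x").fit(df)
    df2 = df.assign(population=df["population"] * 1000)
    m2 = cc.FixedEffectsPoisson(exposure="x").fit(df2)
    assert m1.coef_["x"] == pytest.approx(m2.coef_["x"], rel=1e-8)


def test_null_calibration_small():
    """With no true effect, estimates centre on RR 1 and the 95% CI
    covers 1 in most replicates."""
    cover, est = 0, []
    n = 30
    for s in range(n):
        df = _pure_panel(seed=100 + s, M=50, T=8, rr=1.0)
        m = cc.FixedEffectsPoisson(exposure="x").fit(df)
        b = m.coef_["x"]
        se = np.sqrt(m.cov_.loc["x", "x"])
        est.append(b)
        cover += (b - 1.96 * se) <= 0 <= (b + 1.96 * se)
    assert abs(np.mean(est)) < 0.01
    assert cover >= int(0.8 * n)


def test_cluster_se_exceeds_classical_under_overdispersion():
    """Gamma-frailty panels have within-municipality correlation; in
    aggregate the cluster-robust SE must exceed the classical one."""
    ratios = []
    for s in range(5):
        cfg = cc.SimConfig(n_municipalities=120, seed=300 + s,
                           frailty_shape=3.0, covariate_log_effects={})
        panel, _ = cc.generate_panel(cfg)
        p2 = cc.ExposureTransformer().fit(panel).transform(panel)
        m = cc.FixedEffectsPoisson(covariates=()).fit(p2)
        i = m.terms_.index("coverage_level[consolidated]")
        ratios.append(np.sqrt(m.cov_.iloc[i, i]
                              / m.cov_classical_.iloc[i, i]))
    assert np.mean(ratios) > 1.2


def test_collinear_design_names_columns():
    df = _pure_panel(seed=6, M=10, T=6)
    df["x_copy"] = df["x"]
    with pytest.raises(ValueError, match="x_copy|x"):
        cc.FixedEffectsPoisson(exposure="x", covariates=("x_copy",)).fit(df)


def test_all_zero_outcome_municipality_dropped():
    df = _pure_panel(seed=7, M=10, T=6)
    df.loc[df["municipality"] == "M000", "deaths"] = 0
    m = cc.FixedEffectsPoisson(exposure="x").fit(df)
    assert m.dropped_zero_outcome_municipalities_ == 1
    assert m.n_municipalities_ == 9
    assert np.isneginf(m.alpha_.get("M000", -np.inf))


def test_zero_denominator_dropped():
    df = _pure_panel(seed=8, M=10, T=6)
    df.loc[df.index[:3], "population"] = 0
    m = cc.FixedEffectsPoisson(exposure="x").fit(df)
    assert m.dropped_zero_denominator_ == 3


def test_predicted_totals_match_observed(fitted, prepared):
    """The profile fixed effects force predicted municipal totals to
    equal observed totals."""
    df, _, _ = prepared
    mu = fitted.predict_expected(df)
    assert mu.sum() == pytest.approx(df["deaths"].sum(), rel=1e-9)


def test_stratified_fits(prepared):
    df, _, _ = prepared
    base = cc.FixedEffectsPoisson(covariates=())
    fits = cc.fit_stratified(df, base)
    assert set(fits) == {"under5", "5_69", "70plus", "overall"}
    # identical outcome columns give identical results
    df2 = df.assign(deaths_5_69=df["deaths_70plus"],
                    pop_5_69=df["pop_70plus"])
    fits2 = cc.fit_stratified(df2, base, {
        "a": ("deaths_5_69", "pop_5_69"), "b": ("deaths_70plus", "pop_70plus")})
    pd.testing.assert_series_equal(fits2["a"].coef_, fits2["b"].coef_)


def test_stratified_recovers_distinct_group_effects():
    """Generator with per-age-group RRs (0.7, 0.9, 0.65) at consolidated
    coverage: each group fit recovers its own effect within the CI."""
    levels = ("low", "intermediate", "high", "consolidated")
    per_group = {
        "under5": {"low": 1.0, "intermediate": 0.9, "high": 0.8,
                   "consolidated": 0.7},
        "5_69": {"low": 1.0, "intermediate": 0.97, "high": 0.93,
                 "consolidated": 0.9},
        "70plus": {"low": 1.0, "intermediate": 0.9, "high": 0.8,
                   "consolidated": 0.65},
    }
    cfg = cc.SimConfig(n_municipalities=300, seed=42,
                       true_rr_by_age_group=per_group,
                       covariate_log_effects={})
    panel, _ = cc.generate_panel(cfg)
    p2 = cc.ExposureTransformer().fit(panel).transform(panel)
    fits = cc.fit_stratified(p2, cc.FixedEffectsPoisson(covariates=()))
    for grp, true in (("under5", 0.7), ("5_69", 0.9), ("70plus", 0.65)):
        rr = fits[grp].rate_ratios().set_index("term") \
            .loc["coverage_level[consolidated]"]
        assert rr["ci_low"] < true < rr["ci_high"], grp


def test_missing_model_column_named(panel):
    with pytest.raises(ValueError, match="coverage_level"):
        cc.FixedEffectsPoisson().fit(panel)   # exposure not yet computed


def test_modelspec_roundtrip(two_by_two):
    spec = cc.ModelSpec(exposure="exposed", covariates=())
    m = cc.fit(two_by_two, spec)
    assert np.exp(m.coef_["exposed"]) == pytest.approx(0.8, abs=1e-9)
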