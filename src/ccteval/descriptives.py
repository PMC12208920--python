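"""Age-standardised rates and panel summary tables.

Direct standardisation: the overall rate is the dot product of
age-specific rates with a reference age structure.  The under-5 group
uses livebirths as its person denominator; the other groups use their
age-group population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: outcome-column / denominator-column pairs per age group
AGE_GROUPS = {
    "deaths": {
        "under5": ("deaths_under5", "livebirths"),
        "5_69": ("deaths_5_69", "pop_5_69"),
        "70plus": ("deaths_70plus", "pop_70plus"),
    },
    "hospitalisations": {
        "under5": ("hosp_under5", "livebirths"),
        "5_69": ("hosp_5_69", "pop_5_69"),
        "70plus": ("hosp_70plus", "pop_70plus"),
    },
}


def age_standardize(age_specific_rates, age_weights) -> float:
    """Directly standardised rate: sum_g w_g * r_g.

    Weights must be nonnegative and sum to 1 over the same age
    partition as the rates.
    """
    r = np.asarray(age_specific_rates, dtype=float)
    w = np.asarray(age_weights, dtype=float)
    if r.shape != w.shape:
        raise ValueError(
            f"age partitions differ: {r.shape[0]} rates vs {w.shape[0]} weights")
    if np.any(w < 0):
        raise ValueError("age weights must be nonnegative")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError(f"age weights must sum to 1 (got {w.sum():.6f})")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    return float(r @ w)


def reference_weights(panel: pd.DataFrame, outcome: str = "deaths") -> pd.Series:
    """Reference age structure: pooled person denominators of the panel.

    The default standard population is the analysed panel itself, pooled
    over the study period (configurable by passing explicit weights to
    the rate functions).
    """
    groups = AGE_GROUPS[outcome]
    totals = {g: float(panel[den].sum()) for g, (_, den) in groups.items()}
    s = pd.Series(totals)
    return s / s.sum()


def age_standardized_rates(panel: pd.DataFrame, outcome: str = "deaths",
                           weights: pd.Series | None = None,
                           by=("municipality", "year")) -> pd.DataFrame:
    """Crude age-specific and standardised rates per 1000, per group key.

    Returns one row per ``by`` key with ``rate_<group>`` columns and an
    ``asmr`` column (the standardised overall rate).
    """
    groups = AGE_GROUPS[outcome]
    if weights is None:
        weights = reference_weights(panel, outcome)
    weights = weights.reindex(list(groups))
    if weights.isna().any():
        raise ValueError("weights must cover every age group")

    agg = {}
    for g, (num, den) in groups.items():
        agg[f"_n_{g}"] = (num, "sum")
        agg[f"_d_{g}"] = (den, "sum")
    df = panel.groupby(list(by)).agg(**agg).reset_index()
    rates = {}
    for g in groups:
        num = df[f"_n_{g}"].to_numpy(float)
        den = df[f"_d_{g}"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rates[g] = np.where(den > 0, 1000.0 * num / den, 0.0)
        df[f"rate_{g}"] = rates[g]
    df["asmr"] = sum(weights[g] * df[f"rate_{g}"] for g in groups)
    return df[[*by, *(f"rate_{g}" for g in groups), "asmr"]]


def change_summary(first_mean: float, last_mean: float) -> tuple[float, float]:
    """Absolute and relative (%) change between two anchor means.

    Relative change is ``100 * absolute / first_mean``; both are rounded
    to two decimals for presentation.
    """
    absolute = last_mean - first_mean
    relative = 100.0 * absolute / first_mean if first_mean != 0 else 0.0
    return round(absolute + 0.0, 2), round(relative + 0.0, 2)


def summarize(panel: pd.DataFrame, variables, anchor_years) -> pd.DataFrame:
    """Per-year mean (SD) across municipalities plus anchor-year changes.

    Unweighted municipal means per year; absolute and relative change
    computed between the two anchor years.
    """
    a, b = anchor_years
    years = sorted(panel["year"].unique())
    for y in (a, b):
        if y not in years:
            raise ValueError(f"anchor year {y} not present in the panel")
    rows = []
    for var in variables:
        if var not in panel.columns:
            raise ValueError(f"variable '{var}' not present in the panel")
        per_year = panel.groupby("year")[var].agg(["mean", "std"])
        absolute, relative = change_summary(per_year.loc[a, "mean"],
                                            per_year.loc[b, "mean"])
        row = {"variable": var,
               f"mean_{a}": per_year.loc[a, "mean"],
               f"sd_{a}": per_year.loc[a, "std"],
               f"mean_{b}": per_year.loc[b, "mean"],
               f"sd_{b}": per_year.loc[b, "std"],
               "absolute_change": absolute,
               "relative_change_pct": relative}
        rows.append(row)
    return pd.DataFrame(rows)
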