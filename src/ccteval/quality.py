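"""Vital-statistics adequacy screening.

A municipality is analysable only if its civil registration and vital
statistics look complete.  The multidimensional criterion evaluates,
per municipality and averaged over an evaluation window:

1. the age-standardised mortality rate (a floor — implausibly low ASMR
   signals death under-registration),
2. the ratio of registered to demographically estimated births (a floor),
3. the percentage of deaths with ill-defined cause (a ceiling), and
4. the mean adverse deviation of the three previous dimensions from the
   panel norm, in panel SD units (a ceiling on the composite).

Municipalities are excluded, never adjusted.  The default thresholds
are documented placeholders: the criterion's published numeric values
live outside the sources this package reimplements, so they must be
supplied via configuration when reproducing a specific study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .descriptives import age_standardized_rates

DIMENSIONS = ["asmr", "birth_registration_ratio", "ill_defined_pct",
              "mean_deviation"]


@dataclass
class QualityCriteria:
    """Thresholds of the four-dimension adequacy criterion.

    Defaults are non-authoritative placeholders tuned for synthetic
    panels; see the module docstring.
    """

    min_asmr: float = 4.0
    min_birth_registration_ratio: float = 0.9
    max_ill_defined_pct: float = 10.0
    max_mean_deviation: float = 1.5
    evaluation_window: tuple | None = None   # (first, last) year inclusive

    def __post_init__(self):
        for name in ("min_asmr", "min_birth_registration_ratio",
                     "max_ill_defined_pct", "max_mean_deviation"):
            v = getattr(self, name)
            if not math.isfinite(v) and name != "max_mean_deviation":
                raise ValueError(f"{name} must be finite")
        if not (0 < self.min_birth_registration_ratio <= 1.5):
            raise ValueError("min_birth_registration_ratio must be in (0, 1.5]")
        if not (0 <= self.max_ill_defined_pct <= 100):
            raise ValueError("max_ill_defined_pct must be in [0, 100]")

    @classmethod
    def vacuous(cls) -> "QualityCriteria":
        """Criteria under which every municipality passes."""
        return cls(min_asmr=0.0, min_birth_registration_ratio=1e-9,
                   max_ill_defined_pct=100.0, max_mean_deviation=math.inf)


@dataclass
class QualityReport:
    table: pd.DataFrame          # one row per municipality
    criteria: QualityCriteria
    n_pass: int = field(init=False)

    def __post_init__(self):
        self.n_pass = int(self.table["passed"].sum())

    def passing_municipalities(self) -> list:
        return list(self.table.loc[self.table["passed"], "municipality"])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["failing_dimensions"] = out["failing_dimensions"].map(";".join)
        out.to_csv(path, index=False)


_REQUIRED = ["deaths", "ill_defined_deaths", "livebirths", "estimated_births"]


def assess(panel: pd.DataFrame, criteria: QualityCriteria | None = None
           ) -> QualityReport:
    """Evaluate every municipality on the four-dimension criterion.

    Dimension values are averaged over the evaluation window before
    thresholding; the report lists every failing dimension.
    """
    criteria = criteria or QualityCriteria()
    missing = [c for c in _REQUIRED if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required column(s): {missing}")

    window = criteria.evaluation_window
    if window is not None:
        lo, hi = window
        panel = panel[(panel["year"] >= lo) & (panel["year"] <= hi)]
        if panel.empty:
            raise ValueError(f"evaluation window {window} selects no records")

    asmr = (age_standardized_rates(panel, outcome="deaths")
            .groupby("municipality")["asmr"].mean())
    sums = panel.groupby("municipality")[
        ["deaths", "ill_defined_deaths", "livebirths", "estimated_births"]
    ].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ill_pct = np.where(sums["deaths"] > 0,
                           100.0 * sums["ill_defined_deaths"] / sums["deaths"],
                           0.0)
        reg_ratio = np.where(sums["estimated_births"] > 0,
                             sums["livebirths"] / sums["estimated_births"],
                             0.0)
    table = pd.DataFrame({
        "municipality": sums.index,
        "asmr": asmr.reindex(sums.index).to_numpy(),
        "birth_registration_ratio": reg_ratio,
        "ill_defined_pct": ill_pct,
    }).reset_index(drop=True)

    # composite: mean adverse z-score of the three raw dimensions
    # (low ASMR, low registration and high ill-defined are adverse)
    zs = []
    for col, adverse_low in (("asmr", True),
                             ("birth_registration_ratio", True),
                             ("ill_defined_pct", False)):
        v = table[col].to_numpy(float)
        sd = v.std(ddof=0)
        z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
        zs.append(-z if adverse_low else z)
    table["mean_deviation"] = np.mean(zs, axis=0)

    fails = {
        "asmr": table["asmr"] < criteria.min_asmr,
        "birth_registration_ratio":
            table["birth_registration_ratio"]
            < criteria.min_birth_registration_ratio,
        "ill_defined_pct":
            table["ill_defined_pct"] > criteria.max_ill_defined_pct,
        "mean_deviation":
            table["mean_deviation"] > criteria.max_mean_deviation,
    }
    failing = [[d for d in DIMENSIONS if fails[d].iloc[i]]
               for i in range(len(table))]
    table["failing_dimensions"] = failing
    table["passed"] = [len(f) == 0 for f in failing]
    return QualityReport(table=table, criteria=criteria)


def filter_panel(panel: pd.DataFrame, report: QualityReport) -> pd.DataFrame:
    """Keep only records of municipalities that pass the criterion."""
    panel_m = set(panel["municipality"].unique())
    report_m = set(report.table["municipality"])
    if not panel_m <= report_m:
        extra = sorted(panel_m - report_m)[:5]
        raise ValueError(
            f"report does not cover the panel; e.g. missing {extra}")
    keep = set(report.passing_municipalities())
    return panel[panel["municipality"].isin(keep)].reset_index(drop=True)


class VitalStatisticsFilter(BaseEstimator):
    """Estimator wrapper: fit() assesses, transform() filters."""

    def __init__(self, min_asmr=4.0, min_birth_registration_ratio=0.9,
                 max_ill_defined_pct=10.0, max_mean_deviation=1.5,
                 evaluation_window=None):
        self.min_asmr = min_asmr
        self.min_birth_registration_ratio = min_birth_registration_ratio
        self.max_ill_defined_pct = max_ill_defined_pct
        self.max_mean_deviation = max_mean_deviation
        self.evaluation_window = evaluation_window

    def _criteria(self) -> QualityCriteria:
        return QualityCriteria(
            min_asmr=self.min_asmr,
            min_birth_registration_ratio=self.min_birth_registration_ratio,
            max_ill_defined_pct=self.max_ill_defined_pct,
            max_mean_deviation=self.max_mean_deviation,
            evaluation_window=self.evaluation_window)

    def fit(self, panel: pd.DataFrame, y=None):
        self.report_ = assess(panel, self._criteria())
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "report_"):
            raise RuntimeError("VitalStatisticsFilter is not fitted")
        return filter_panel(panel, self.report_)
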