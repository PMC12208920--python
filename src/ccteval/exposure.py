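"""Programme-exposure coding.

Two continuous exposure measures are derived per municipality-year:

* **target coverage** ``C = 100 * enrolled / eligible`` (percent of the
  programme's target population actually enrolled), and
* **adequacy** ``A = transferred / enrolled`` (mean monthly transfer per
  enrolled family, BRL).

Each is categorised into four dose-response levels (low, intermediate,
high, consolidated) and the two dimensions are crossed into a four-group
adequacy-by-coverage interaction.  Adjusting covariates are dichotomised
at their pooled-panel median (or mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

LEVELS = ["low", "intermediate", "high", "consolidated"]

#: Coverage cut-points in percent: [0,30) / [30,70) / [70,100) / [100,inf).
DEFAULT_COVERAGE_CUTS = (30.0, 70.0, 100.0)

#: Published adequacy quartile cut-points (BRL/family/month) usable as an
#: explicit category spec when pooled quartiles should not be recomputed.
REFERENCE_ADEQUACY_CUTS = (61.44, 99.13, 151.23)

INTERACTION_GROUPS = [
    "low_adequacy_low_coverage",
    "low_adequacy_high_coverage",
    "high_adequacy_low_coverage",
    "high_adequacy_high_coverage",
]


@dataclass
class CategorySpec:
    """How exposures are categorised and covariates split.

    ``adequacy_cuts=None`` means: compute the three quartile cut-points
    once over the pooled panel and freeze them.
    """

    coverage_cuts: tuple = DEFAULT_COVERAGE_CUTS
    adequacy_cuts: tuple | None = None
    covariate_split: str = "median"          # or "mean"
    interaction_rule: str = "median"         # or "collapse"

    def __post_init__(self):
        cuts = tuple(self.coverage_cuts)
        if not all(a < b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("coverage_cuts must be strictly increasing")
        if self.adequacy_cuts is not None:
            ac = tuple(self.adequacy_cuts)
            if not all(a < b for a, b in zip(ac, ac[1:])):
                raise ValueError("adequacy_cuts must be strictly increasing")
        if self.covariate_split not in ("median", "mean"):
            raise ValueError("covariate_split must be 'median' or 'mean'")
        if self.interaction_rule not in ("median", "collapse"):
            raise ValueError("interaction_rule must be 'median' or 'collapse'")


def _categorize(values, cuts, what: str) -> pd.Categorical:
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"negative {what} value(s); {what} must be >= 0")
    cuts = tuple(cuts)
    bins = [-np.inf, *cuts, np.inf]
    # closed-left / open-right bins: [0,c1), [c1,c2), [c2,c3), [c3,inf)
    codes = np.searchsorted(np.asarray(cuts), arr, side="right")
    out = pd.Categorical.from_codes(codes, categories=LEVELS, ordered=True)
    del bins
    return out


def categorize_coverage(coverage, cuts=DEFAULT_COVERAGE_CUTS):
    """Map coverage (%) to a dose level; values above 100 are consolidated.

    Bins are closed-left/open-right: [0,30), [30,70), [70,100), [100,inf).
    Scalar in, scalar out; array-like in, ordered Categorical out.
    """
    scalar = np.isscalar(coverage)
    cat = _categorize(np.atleast_1d(coverage), cuts, "coverage")
    return cat[0] if scalar else cat


def categorize_adequacy(adequacy, cuts=REFERENCE_ADEQUACY_CUTS):
    """Map adequacy (BRL/family/month) to a dose level at the given cuts."""
    scalar = np.isscalar(adequacy)
    cat = _categorize(np.atleast_1d(adequacy), cuts, "adequacy")
    return cat[0] if scalar else cat


def adequacy_quartiles(adequacy) -> tuple:
    """Pooled 25/50/75 percentile cut-points, frozen once per panel."""
    arr = np.asarray(adequacy, dtype=float)
    arr = arr[np.isfinite(arr)]
    q = np.percentile(arr, [25, 50, 75])
    return tuple(float(x) for x in q)


def interaction_group(coverage_level, adequacy_level, rule: str = "collapse"):
    """Cross the two categorical dose levels into the 2x2 interaction.

    The categorical ``collapse`` rule treats {low, intermediate} as the
    low arm and {high, consolidated} as the high arm of each dimension.
    (The median rule operates on the continuous variables and lives in
    :class:`ExposureTransformer`.)
    """
    if rule != "collapse":
        raise ValueError("only the 'collapse' rule is defined on levels; "
                         "use ExposureTransformer for the median rule")

    def _one(cl, al):
        if cl not in LEVELS or al not in LEVELS:
            raise ValueError(f"invalid level: {cl!r}, {al!r}")
        hi_c = cl in ("high", "consolidated")
        hi_a = al in ("high", "consolidated")
        return INTERACTION_GROUPS[2 * hi_a + hi_c]

    if isinstance(coverage_level, str):
        return _one(coverage_level, adequacy_level)
    return pd.Categorical(
        [_one(c, a) for c, a in zip(coverage_level, adequacy_level)],
        categories=INTERACTION_GROUPS)


def compute_exposures(panel: pd.DataFrame) -> pd.DataFrame:
    """Continuous coverage and adequacy per municipality-year.

    Records with ``eligible == 0`` but ``enrolled > 0`` have undefined
    coverage and are excluded with a warning.  ``enrolled == 0`` gives
    adequacy 0 and sets ``adequacy_undefined``.
    """
    required = ["bfp_enrolled", "bfp_eligible", "bfp_transferred"]
    missing = [c for c in required if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing programme column(s): {missing}")
    out = panel[["municipality", "year"] if "municipality" in panel.columns
                else panel.columns[:0]].copy()
    enrolled = panel["bfp_enrolled"].to_numpy(float)
    eligible = panel["bfp_eligible"].to_numpy(float)
    transferred = panel["bfp_transferred"].to_numpy(float)
    if np.any(enrolled < 0):
        raise ValueError("bfp_enrolled must be >= 0")

    undefined = (eligible == 0) & (enrolled > 0)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} record(s) with eligible=0 and enrolled>0 "
            "have undefined coverage and were excluded", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coverage = np.where(eligible > 0, 100.0 * enrolled / eligible, 0.0)
        adequacy = np.where(enrolled > 0, transferred / enrolled, 0.0)
    out["target_coverage"] = coverage
    out["adequacy"] = adequacy
    out["adequacy_undefined"] = enrolled == 0
    return out.loc[~undefined].reset_index(drop=True)


class ExposureTransformer(BaseEstimator, TransformerMixin):
    """Learn category cut-points on a panel, then label exposures.

    fit() freezes adequacy quartile cut-points (when not given
    explicitly) and, for the median interaction rule, the pooled medians
    of the two continuous exposures.  transform() appends
    ``target_coverage``, ``adequacy``, ``coverage_level``,
    ``adequacy_level`` and ``interaction_group`` columns.
    """

    def __init__(self, coverage_cuts=DEFAULT_COVERAGE_CUTS,
                 adequacy_cuts=None, interaction_rule="median"):
        self.coverage_cuts = coverage_cuts
        self.adequacy_cuts = adequacy_cuts
        self.interaction_rule = interaction_rule

    def fit(self, panel: pd.DataFrame, y=None):
        CategorySpec(coverage_cuts=self.coverage_cuts,
                     adequacy_cuts=self.adequacy_cuts,
                     interaction_rule=self.interaction_rule)
        expo = compute_exposures(panel)
        if self.adequacy_cuts is None:
            self.adequacy_cuts_ = adequacy_quartiles(expo["adequacy"])
        else:
            self.adequacy_cuts_ = tuple(self.adequacy_cuts)
        self.coverage_median_ = float(np.median(expo["target_coverage"]))
        self.adequacy_median_ = float(np.median(expo["adequacy"]))
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "adequacy_cuts_"):
            raise RuntimeError("ExposureTransformer is not fitted")
        expo = compute_exposures(panel)
        keys = ["municipality", "year"]
        out = panel.merge(expo, on=keys, how="inner")
        out["coverage_level"] = categorize_coverage(
            out["target_coverage"], self.coverage_cuts)
        out["adequacy_level"] = categorize_adequacy(
            out["adequacy"], self.adequacy_cuts_)
        if self.interaction_rule == "median":
            hi_c = out["target_coverage"].to_numpy() >= self.coverage_median_
            hi_a = out["adequacy"].to_numpy() >= self.adequacy_median_
            codes = 2 * hi_a.astype(int) + hi_c.astype(int)
            out["interaction_group"] = pd.Categorical.from_codes(
                codes, categories=INTERACTION_GROUPS)
        else:
            out["interaction_group"] = interaction_group(
                out["coverage_level"], out["adequacy_level"], rule="collapse")
        return out


class CovariateDichotomizer(BaseEstimator, TransformerMixin):
    """Split covariates at their pooled-panel median (or mean) into 0/1.

    Values at or above the split statistic code 1.  Constant covariates
    cannot be split; they are dropped from the model-candidate list with
    a warning and recorded in ``dropped_``.
    """

    def __init__(self, columns=None, stat="median"):
        self.columns = columns
        self.stat = stat

    def fit(self, panel: pd.DataFrame, y=None):
        if self.stat not in ("median", "mean"):
            raise ValueError("stat must be 'median' or 'mean'")
        cols = list(self.columns) if self.columns is not None else [
            c for c in panel.columns
            if c in _default_covariates and c in panel.columns]
        thresholds, dropped = {}, []
        for c in cols:
            v = panel[c].to_numpy(float)
            v = v[np.isfinite(v)]
            if v.size == 0 or np.all(v == v[0]):
                dropped.append(c)
                continue
            thresholds[c] = float(np.median(v) if self.stat == "median"
                                  else np.mean(v))
        if dropped:
            warnings.warn(f"constant covariate(s) dropped: {dropped}",
                          stacklevel=2)
        self.thresholds_ = thresholds
        self.dropped_ = dropped
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("CovariateDichotomizer is not fitted")
        out = panel.copy()
        for c, thr in self.thresholds_.items():
            out[c] = (out[c].to_numpy(float) >= thr).astype(int)
        out.attrs["covariate_split"] = {"stat": self.stat,
                                        "thresholds": dict(self.thresholds_)}
        return out


# late import-free default; mirrors io.COVARIATE_COLUMNS without a cycle
_default_covariates = [
    "poverty_rate", "illiteracy_rate", "gini", "urbanization_rate",
    "piped_water", "sanitation", "physicians_per_1000", "beds_per_1000",
    "bpc_coverage", "esf_coverage", "fertility_rate",
]


def dichotomize_covariates(panel, columns=None, stat="median"):
    """Functional wrapper over :class:`CovariateDichotomizer`."""
    d = CovariateDichotomizer(columns=columns, stat=stat)
    return d.fit(panel).transform(panel)
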