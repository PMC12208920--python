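"""Difference-in-differences with propensity-score matching.

Triangulation of the panel-regression estimates: municipalities with
low programme coverage at the first anchor year are compared with
medium/high-coverage municipalities, matched on baseline covariates via
a logistic propensity model, and the pre/post change in log rates is
differenced between arms.  The DiD coefficient exponentiates to a rate
ratio comparable with the Poisson model's.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .exposure import categorize_coverage


@dataclass
class MatchSpec:
    covariates: tuple = ()
    caliper: float = 0.2          # in SD of the linear propensity
    ratio: int = 1
    replacement: bool = False

    def __post_init__(self):
        if self.caliper <= 0:
            raise ValueError("caliper must be > 0")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass
class DiDResult:
    estimate: float               # on the log-rate scale
    se: float
    ci_low: float
    ci_high: float
    rr: float                     # exp(estimate)
    rr_low: float
    rr_high: float
    n_pairs: int
    n_dropped: int
    balance: pd.DataFrame         # SMD pre/post per covariate


class SeparationError(RuntimeError):
    pass


def estimate_propensity(baseline: pd.DataFrame, covariates,
                        treatment_col: str = "treated") -> pd.Series:
    """Logistic propensity scores, fitted by IRLS.

    Raises :class:`SeparationError` when coefficients diverge (perfect
    separation), suggesting covariate reduction.
    """
    X = sm.add_constant(baseline[list(covariates)].to_numpy(float))
    yv = baseline[treatment_col].to_numpy(float)
    model = sm.GLM(yv, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 15:
        raise SeparationError(
            "propensity model shows separation (diverging coefficients); "
            "reduce or coarsen the covariate set")
    scores = pd.Series(res.fittedvalues,
                       index=baseline["municipality"].to_numpy(),
                       name="propensity")
    return scores.clip(1e-12, 1 - 1e-12)


def _linear(scores: pd.Series) -> pd.Series:
    return np.log(scores / (1 - scores))


def match(scores: pd.Series, treated: pd.Series, spec: MatchSpec | None = None
          ) -> pd.DataFrame:
    """Greedy nearest-neighbour matching on the linear propensity.

    Without replacement by default; pairs beyond the caliper (in SD of
    the linear propensity) are discarded.  Deterministic: treated units
    are processed in ascending id order and distance ties go to the
    control with the lower id.
    """
    spec = spec or MatchSpec()
    lp = _linear(scores.astype(float))
    sd = float(lp.std(ddof=0))
    caliper_abs = spec.caliper * sd if sd > 0 else np.inf
    treated = treated.reindex(scores.index)
    t_ids = sorted(scores.index[treated.astype(bool)])
    c_ids = sorted(scores.index[~treated.astype(bool)])
    pairs = []
    for _ in range(spec.ratio):
        available = list(c_ids)
        for t in t_ids:
            if not available:
                break
            d = np.abs(lp.loc[available].to_numpy() - lp.loc[t])
            j = int(np.argmin(d))       # ties: first = lowest id (sorted)
            if d[j] <= caliper_abs:
                c = available[j]
                pairs.append((t, c, float(d[j])))
                if not spec.replacement:
                    available.remove(c)
        if not spec.replacement:
            used = {c for _, c, _ in pairs}
            c_ids = [c for c in c_ids if c not in used]
    if not pairs:
        warnings.warn("no matches within the caliper", stacklevel=2)
    out = pd.DataFrame(pairs, columns=["treated", "control", "distance"])
    out["pair"] = np.arange(len(out))
    return out


def standardized_mean_differences(baseline: pd.DataFrame, covariates,
                                  treatment_col="treated",
                                  keep: set | None = None) -> pd.Series:
    """|SMD| per covariate; ``keep`` restricts to matched municipalities."""
    df = baseline
    if keep is not None:
        df = df[df["municipality"].isin(keep)]
    t = df[df[treatment_col].astype(bool)]
    c = df[~df[treatment_col].astype(bool)]
    out = {}
    for v in covariates:
        mt, mc = t[v].mean(), c[v].mean()
        pooled = np.sqrt((t[v].var(ddof=1) + c[v].var(ddof=1)) / 2)
        out[v] = abs(mt - mc) / pooled if pooled > 0 else 0.0
    return pd.Series(out, name="smd")


def did_estimate(panel: pd.DataFrame, pairs: pd.DataFrame, anchor_years,
                 outcome: str = "deaths", denominator: str = "population",
                 balance: pd.DataFrame | None = None) -> DiDResult:
    """DiD on log rates over the matched set.

    (treated post - pre) minus (control post - pre) estimated by OLS of
    ``log(1000 * outcome / denominator)`` on treated, post and their
    interaction, SE clustered on matched pair; exponentiated to an
    RR-style effect.  Municipalities missing an anchor year (or with a
    zero count there) are dropped with a logged count.
    """
    pre, post = anchor_years
    panel = panel.drop(columns=[c for c in ("treated", "pair")
                                if c in panel.columns])
    roles = pd.concat([
        pd.DataFrame({"municipality": pairs["treated"], "treated": 1,
                      "pair": pairs["pair"]}),
        pd.DataFrame({"municipality": pairs["control"], "treated": 0,
                      "pair": pairs["pair"]}),
    ])
    df = panel[panel["year"].isin([pre, post])].merge(roles, on="municipality")
    rate = 1000.0 * df[outcome].to_numpy(float) \
        / df[denominator].to_numpy(float)
    df = df.assign(rate=rate)
    ok = df["rate"] > 0
    have_both = (df[ok].groupby("municipality")["year"].nunique() == 2)
    keep_m = set(have_both.index[have_both])
    dropped = df["municipality"].nunique() - len(keep_m)
    df = df[ok & df["municipality"].isin(keep_m)]
    # drop pairs that lost a member
    full_pairs = df.groupby("pair")["municipality"].nunique()
    whole = set(full_pairs.index[full_pairs == 2])
    df = df[df["pair"].isin(whole)]
    if df.empty:
        raise ValueError("no complete matched pairs with both anchor years")

    y = np.log(df["rate"].to_numpy())
    tr = df["treated"].to_numpy(float)
    po = (df["year"] == post).to_numpy(float)
    X = sm.add_constant(np.column_stack([tr, po, tr * po]))
    res = sm.OLS(y, X).fit(cov_type="cluster",
                           cov_kwds={"groups": df["pair"].to_numpy()})
    est, se = float(res.params[3]), float(res.bse[3])
    lo, hi = est - 1.96 * se, est + 1.96 * se
    return DiDResult(estimate=est, se=se, ci_low=lo, ci_high=hi,
                     rr=float(np.exp(est)), rr_low=float(np.exp(lo)),
                     rr_high=float(np.exp(hi)), n_pairs=len(whole),
                     n_dropped=int(dropped),
                     balance=balance if balance is not None
                     else pd.DataFrame())


class PropensityScoreMatcher(BaseEstimator):
    """Estimator wrapper: fit() learns scores and pairs at baseline.

    The treated arm is "coverage beyond low at the anchor year"
    (intermediate, high or consolidated) by default.
    """

    def __init__(self, covariates=(), anchor_year=2004, caliper=0.2,
                 ratio=1, replacement=False, treatment_levels=(
                     "intermediate", "high", "consolidated")):
        self.covariates = covariates
        self.anchor_year = anchor_year
        self.caliper = caliper
        self.ratio = ratio
        self.replacement = replacement
        self.treatment_levels = treatment_levels

    def fit(self, panel: pd.DataFrame, y=None):
        base = panel[panel["year"] == self.anchor_year].copy()
        if base.empty:
            raise ValueError(f"anchor year {self.anchor_year} not in panel")
        if "coverage_level" in base.columns:
            level = base["coverage_level"]
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                cov = np.where(base["bfp_eligible"] > 0,
                               100.0 * base["bfp_enrolled"]
                               / base["bfp_eligible"], 0.0)
            level = categorize_coverage(cov)
        base["treated"] = np.asarray(
            [l in self.treatment_levels for l in np.asarray(level)], dtype=int)
        spec = MatchSpec(covariates=tuple(self.covariates),
                         caliper=self.caliper, ratio=self.ratio,
                         replacement=self.replacement)
        scores = estimate_propensity(base, self.covariates)
        treated = pd.Series(base["treated"].to_numpy(),
                            index=base["municipality"].to_numpy())
        pairs = match(scores, treated, spec)
        matched = set(pairs["treated"]) | set(pairs["control"])
        self.baseline_ = base
        self.scores_ = scores
        self.pairs_ = pairs
        self.balance_ = pd.DataFrame({
            "smd_pre": standardized_mean_differences(
                base, self.covariates),
            "smd_post": standardized_mean_differences(
                base, self.covariates, keep=matched),
        })
        return self

    def estimate(self, panel: pd.DataFrame, anchor_years,
                 outcome="deaths", denominator="population") -> DiDResult:
        if not hasattr(self, "pairs_"):
            raise RuntimeError("PropensityScoreMatcher is not fitted")
        return did_estimate(panel, self.pairs_, anchor_years,
                            outcome=outcome, denominator=denominator,
                            balance=self.balance_)


def optimal_match_bruteforce(scores: pd.Series, treated: pd.Series,
                             caliper_abs: float = np.inf) -> list:
    """Exhaustive minimum-total-distance 1:1 matching (tiny inputs only).

    Independent oracle for :func:`match`; enumerates control
    assignments, so use with <= 8 units.
    """
    lp = _linear(scores.astype(float))
    t_ids = sorted(scores.index[treated.astype(bool)])
    c_ids = sorted(scores.index[~treated.astype(bool)])
    best, best_cost = [], np.inf
    k = min(len(t_ids), len(c_ids))
    for combo in itertools.permutations(c_ids, k):
        pairs, cost = [], 0.0
        for t, c in zip(t_ids, combo):
            d = abs(lp.loc[t] - lp.loc[c])
            if d <= caliper_abs:
                pairs.append((t, c))
                cost += d
        key = (-len(pairs), cost)
        if key < (-len(best), best_cost):
            best, best_cost = pairs, cost
    return best
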