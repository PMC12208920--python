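"""Fixed-effects Poisson regression for municipal rate panels.

The estimand is a log-linear model of event counts,

    y_mt ~ Poisson( d_mt * exp(alpha_m + x_mt' beta) )

with person-denominator offset ``d_mt``, municipality intercepts
``alpha_m`` and regressors ``x`` holding the exposure dose indicators,
dichotomised covariates and time controls.  The municipal intercepts are
not estimated as dummies: for the Poisson log link the profile (equiv.
conditional) likelihood eliminates them exactly, reducing each
municipality's contribution to a multinomial term

    ll_m = sum_t y_mt * log p_mt,   p_mt = r_mt / sum_t' r_mt',
    r_mt = d_mt * exp(x_mt' beta),

whose maximiser coincides with the joint MLE of the dummy
parameterisation.  This keeps the design at a handful of columns for
thousands of municipalities.  Inference uses a sandwich covariance with
scores summed within municipality (cluster-robust to overdispersion and
serial correlation); the model-based inverse-information covariance is
kept alongside for diagnostics.

Municipalities with an all-zero outcome carry no information about beta
and are dropped (their profile intercept diverges); the drop count is
logged, as are records removed for missing values or zero denominators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from sklearn.base import BaseEstimator

from .exposure import INTERACTION_GROUPS, LEVELS

logger = logging.getLogger(__name__)

DEFAULT_SHOCK_PERIODS = ((2008, 2009), (2013, 2014), (2015, 2016))

_EXPOSURE_CATEGORIES = {
    "coverage_level": LEVELS,
    "adequacy_level": LEVELS,
    "interaction_group": INTERACTION_GROUPS,
}


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Serialisable description of one model fit (mirrors estimator params)."""

    outcome: str = "deaths"
    denominator: str = "population"
    exposure: str = "coverage_level"
    covariates: tuple = ()
    time_effects: str = "year"           # "year" | "shocks" | "none"
    cluster: str = "municipality"

    def to_estimator(self) -> "FixedEffectsPoisson":
        return FixedEffectsPoisson(
            outcome=self.outcome, denominator=self.denominator,
            exposure=self.exposure, covariates=self.covariates,
            time_effects=self.time_effects)


@dataclass
class FitResult:
    """Frozen view of a converged fit (detached from the estimator)."""

    terms: list
    coef: np.ndarray
    cov_robust: np.ndarray
    cov_classical: np.ndarray
    loglik: float
    n_obs: int
    n_municipalities: int
    n_iter: int
    converged: bool

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))


def _logsumexp_by_group(eta, idx, n_groups):
    mx = np.full(n_groups, -np.inf)
    np.maximum.at(mx, idx, eta)
    s = np.zeros(n_groups)
    np.add.at(s, idx, np.exp(eta - mx[idx]))
    return mx + np.log(s)


class FixedEffectsPoisson(BaseEstimator):
    """Conditional-likelihood fixed-effects Poisson rate model.

    Parameters
    ----------
    outcome, denominator : str
        Count column and strictly positive person-denominator column
        (entering as a log offset).
    exposure : str or None
        Categorical exposure column: ``coverage_level``,
        ``adequacy_level`` or ``interaction_group`` (reference = first
        category), or any other column taken as a continuous regressor,
        or None.
    covariates : sequence of str
        Pre-dichotomised 0/1 covariate columns, entered as given.
    time_effects : {"year", "shocks", "none"}
        "year" adds a full calendar-year indicator set (first observed
        year is the reference); "shocks" adds three economic-shock
        period indicators (2008-09, 2013-14, 2015-16) only.
    cov_type : {"CR3", "CR1"}
        Cluster covariance estimator.  CR3 (default) is a one-step
        delete-one-cluster jackknife, which corrects the finite-G
        downward bias of the plain CR1 sandwich; CR1 is the textbook
        sandwich with a G/(G-1) factor.
    """

    def __init__(self, outcome="deaths", denominator="population",
                 exposure="coverage_level", covariates=(),
                 time_effects="year", shock_periods=DEFAULT_SHOCK_PERIODS,
                 cluster="municipality", cov_type="CR3", max_iter=100,
                 tol=1e-10, gtol=1e-8):
        self.outcome = outcome
        self.denominator = denominator
        self.exposure = exposure
        self.covariates = covariates
        self.time_effects = time_effects
        self.shock_periods = shock_periods
        self.cluster = cluster
        self.cov_type = cov_type
        self.max_iter = max_iter
        self.tol = tol
        self.gtol = gtol

    # -- design -------------------------------------------------------------

    def _exposure_design(self, df: pd.DataFrame):
        cols, names = [], []
        exp_col = self.exposure
        if exp_col is None:
            return cols, names
        if exp_col in _EXPOSURE_CATEGORIES:
            cats = self.exposure_categories_
            values = pd.Categorical(df[exp_col], categories=cats)
            if values.isna().any():
                bad = sorted(set(np.asarray(df[exp_col]))
                             - set(cats))
                raise ValueError(
                    f"exposure value(s) outside the fitted design: {bad}")
            for c in cats[1:]:
                cols.append((np.asarray(values) == c).astype(float))
                names.append(f"{exp_col}[{c}]")
        else:
            cols.append(df[exp_col].to_numpy(float))
            names.append(exp_col)
        return cols, names

    def _time_design(self, df: pd.DataFrame):
        cols, names = [], []
        if self.time_effects == "year":
            year = np.minimum(df["year"].to_numpy(int), self.year_levels_[-1])
            year = np.maximum(year, self.year_levels_[0])
            for y in self.year_levels_[1:]:
                cols.append((year == y).astype(float))
                names.append(f"year[{y}]")
        elif self.time_effects == "shocks":
            year = df["year"].to_numpy(int)
            for a, b in self.shock_periods:
                cols.append(((year >= a) & (year <= b)).astype(float))
                names.append(f"shock[{a}-{b}]")
        elif self.time_effects != "none":
            raise ValueError("time_effects must be 'year', 'shocks' or 'none'")
        return cols, names

    def _build_design(self, df: pd.DataFrame):
        cols, names = self._exposure_design(df)
        for c in self.covariates:
            if c not in df.columns:
                raise ValueError(f"covariate column '{c}' missing from panel")
            cols.append(df[c].to_numpy(float))
            names.append(c)
        tcols, tnames = self._time_design(df)
        cols += tcols
        names += tnames
        X = (np.column_stack(cols) if cols
             else np.empty((len(df), 0)))
        return X, names

    def _model_frame(self, panel: pd.DataFrame) -> pd.DataFrame:
        cols = [self.cluster, "year", self.outcome, self.denominator]
        if self.exposure is not None:
            cols.append(self.exposure)
        cols += list(self.covariates)
        missing = [c for c in cols if c not in panel.columns]
        if missing:
            raise ValueError(f"panel is missing model column(s): {missing}")
        df = panel[cols].copy()
        n0 = len(df)
        df = df.dropna()
        self.dropped_missing_ = n0 - len(df)
        n1 = len(df)
        df = df[df[self.denominator].to_numpy(float) > 0]
        self.dropped_zero_denominator_ = n1 - len(df)
        zero = df.groupby(self.cluster)[self.outcome].transform("sum") == 0
        self.dropped_zero_outcome_municipalities_ = int(
            df.loc[zero, self.cluster].nunique())
        df = df[~zero]
        for what, n in (("missing-value records", self.dropped_missing_),
                        ("zero-denominator records",
                         self.dropped_zero_denominator_),
                        ("all-zero-outcome municipalities",
                         self.dropped_zero_outcome_municipalities_)):
            if n:
                logger.info("fit(%s): dropped %d %s", self.outcome, n, what)
        if df.empty:
            raise ValueError("no usable records after validation drops")
        return df

    # -- likelihood ---------------------------------------------------------

    def _loglik_parts(self, X, log_off, y, idx, G, beta):
        eta = log_off + X @ beta
        lse = _logsumexp_by_group(eta, idx, G)
        logp = eta - lse[idx]
        Yg = np.zeros(G)
        np.add.at(Yg, idx, y)
        ll = float(y @ logp)
        yhat = Yg[idx] * np.exp(logp)
        return ll, yhat, Yg

    def fit(self, panel: pd.DataFrame, y=None):
        if self.exposure is not None and self.exposure not in panel.columns:
            raise ValueError(
                f"panel is missing model column(s): ['{self.exposure}']")
        if self.exposure in _EXPOSURE_CATEGORIES:
            canonical = _EXPOSURE_CATEGORIES[self.exposure]
            observed = set(np.asarray(panel[self.exposure].dropna()))
            present = [c for c in canonical if c in observed]
            if not present:
                raise ValueError(
                    f"exposure column '{self.exposure}' holds no known level")
            # levels absent from the data are dropped from the design;
            # the first present level becomes the reference
            self.exposure_categories_ = present
        df = self._model_frame(panel)
        if self.time_effects == "year":
            self.year_levels_ = np.sort(df["year"].unique())
        X, names = self._build_design(df)
        yv = df[self.outcome].to_numpy(float)
        if np.any(yv < 0) or np.any(yv != np.rint(yv)):
            raise ValueError(f"outcome '{self.outcome}' must hold "
                             "nonnegative integer counts")
        off = df[self.denominator].to_numpy(float)
        log_off = np.log(off)
        groups, idx = np.unique(df[self.cluster].to_numpy(), return_inverse=True)
        G = len(groups)
        if len(df) < 2 * G:
            pass  # single-year municipalities simply contribute nothing
        self._check_collinearity(X, names, idx, G)

        k = X.shape[1]
        beta = np.zeros(k)
        ll, yhat, Yg = self._loglik_parts(X, log_off, yv, idx, G, beta)
        n_iter = 0
        converged = k == 0
        gmax = np.inf
        for n_iter in range(1, self.max_iter + 1 if k else 1):
            resid = yv - yhat
            grad = X.T @ resid
            # information: sum_g [ sum_t w x x' - s_g s_g' / Y_g ]
            A = X.T @ (X * yhat[:, None])
            S = np.zeros((G, k))
            np.add.at(S, idx, X * yhat[:, None])
            nz = Yg > 0
            B = (S[nz] / Yg[nz, None]).T @ S[nz]
            H = A - B
            try:
                step = scipy.linalg.solve(H, grad, assume_a="pos")
            except scipy.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step halving
            scale = 1.0
            for _ in range(40):
                ll_new, yhat_new, _ = self._loglik_parts(
                    X, log_off, yv, idx, G, beta + scale * step)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            dll = ll_new - ll
            ll, yhat = ll_new, yhat_new
            gmax = np.max(np.abs(X.T @ (yv - yhat))) if k else 0.0
            if (abs(dll) <= self.tol * (abs(ll) + 1.0)
                    and gmax <= self.gtol * (1.0 + yv.sum())):
                converged = True
                break
        if not converged and k:
            raise ConvergenceError(
                f"no convergence after {n_iter} iterations "
                f"(max |gradient| = {gmax:.3e})")

        resid = yv - yhat
        A = X.T @ (X * yhat[:, None])
        S = np.zeros((G, k))
        np.add.at(S, idx, X * yhat[:, None])
        nz = Yg > 0
        H = A - (S[nz] / Yg[nz, None]).T @ S[nz]
        Hinv = np.linalg.pinv(H)
        scores = np.zeros((G, k))
        np.add.at(scores, idx, X * resid[:, None])
        if self.cov_type == "CR1":
            meat = scores.T @ scores
            correction = G / (G - 1) if G > 1 else 1.0
            cov_robust = correction * Hinv @ meat @ Hinv
        elif self.cov_type == "CR3":
            # delete-one-cluster jackknife via one-step approximation:
            # beta_{-g} - beta ~= (H - H_g)^{-1} s_g; counters the
            # finite-G downward bias of the plain sandwich
            pseudo = np.empty((G, k))
            for g0 in range(G):
                rows = idx == g0
                Xg, wg = X[rows], yhat[rows]
                Ag = Xg.T @ (Xg * wg[:, None])
                sg_w = (Xg * wg[:, None]).sum(axis=0)
                Hg = Ag - (np.outer(sg_w, sg_w) / Yg[g0]
                           if Yg[g0] > 0 else 0.0)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                    try:
                        pseudo[g0] = scipy.linalg.solve(H - Hg, scores[g0],
                                                        assume_a="pos")
                    except scipy.linalg.LinAlgError:
                        pseudo[g0] = np.linalg.lstsq(H - Hg, scores[g0],
                                                     rcond=None)[0]
            centered = pseudo - pseudo.mean(axis=0)
            cov_robust = (G - 1) / G * centered.T @ centered if G > 1 \
                else centered.T @ centered
        else:
            raise ValueError("cov_type must be 'CR1' or 'CR3'")
        cov_robust = (cov_robust + cov_robust.T) / 2

        self.terms_ = names
        self.coef_ = pd.Series(beta, index=names, name="coef")
        self.cov_ = pd.DataFrame(cov_robust, index=names, columns=names)
        self.cov_classical_ = pd.DataFrame(Hinv, index=names, columns=names)
        self.loglik_ = ll
        self.n_obs_ = len(df)
        self.n_municipalities_ = G
        self.n_iter_ = n_iter
        self.converged_ = converged

        # profile intercepts for prediction: exp(alpha_m) = Y_m / sum r
        eta = log_off + X @ beta
        r_sum = np.zeros(G)
        np.add.at(r_sum, idx, np.exp(eta))
        with np.errstate(divide="ignore"):
            alpha = np.where(Yg > 0, np.log(Yg) - np.log(r_sum), -np.inf)
        self.alpha_ = pd.Series(alpha, index=groups, name="alpha")
        return self

    def _check_collinearity(self, X, names, idx, G):
        if X.shape[1] == 0:
            return
        # within-municipality demeaning removes anything the profile
        # likelihood cannot identify; rank-deficiency there means aliasing
        means = np.zeros((G, X.shape[1]))
        counts = np.zeros(G)
        np.add.at(means, idx, X)
        np.add.at(counts, idx, 1.0)
        Xw = X - (means / counts[:, None])[idx]
        _, R, piv = scipy.linalg.qr(Xw, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xw.shape) * np.finfo(float).eps * 100 \
            if diag.size and diag.max() > 0 else 0.0
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        if diag.size and diag.max() == 0:
            aliased = list(names)
        if aliased:
            raise ValueError(
                f"collinear design; aliased column(s): {sorted(aliased)}")

    # -- post-fit -----------------------------------------------------------

    def _require_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("FixedEffectsPoisson is not fitted")

    def result(self) -> FitResult:
        self._require_fitted()
        return FitResult(
            terms=list(self.terms_), coef=self.coef_.to_numpy().copy(),
            cov_robust=self.cov_.to_numpy().copy(),
            cov_classical=self.cov_classical_.to_numpy().copy(),
            loglik=self.loglik_, n_obs=self.n_obs_,
            n_municipalities=self.n_municipalities_,
            n_iter=self.n_iter_, converged=self.converged_)

    def rate_ratios(self, level: float = 0.95) -> pd.DataFrame:
        """RR = exp(beta) with Wald CIs on the cluster-robust SEs."""
        self._require_fitted()
        z = stats.norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.cov_.to_numpy()))
        coef = self.coef_.to_numpy()
        with np.errstate(divide="ignore"):
            zstat = np.where(se > 0, coef / se, np.inf * np.sign(coef))
        p = 2 * stats.norm.sf(np.abs(zstat))
        return pd.DataFrame({
            "term": self.terms_,
            "RR": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "p": p,
        })

    def predict_expected(self, panel: pd.DataFrame, beta=None,
                         design_override=None) -> np.ndarray:
        """Expected counts with municipality effects held at their
        profiled values; ``beta`` may be a drawn coefficient vector and
        ``design_override`` a callable mutating the model frame before
        the design is built (used for counterfactual exposure)."""
        self._require_fitted()
        df = panel.copy()
        if design_override is not None:
            df = design_override(df)
        X, _ = self._build_design(df)
        b = self.coef_.to_numpy() if beta is None else np.asarray(beta)
        alpha = self.alpha_.reindex(df[self.cluster]).to_numpy()
        if np.isnan(alpha).any():
            missing = sorted(set(df[self.cluster]) - set(self.alpha_.index))
            raise ValueError(f"municipalities not in the fit: {missing[:5]}")
        off = df[self.denominator].to_numpy(float)
        mu = off * np.exp(alpha + X @ b)
        return np.where(np.isfinite(mu), mu, 0.0)

    def design_for(self, panel: pd.DataFrame, design_override=None):
        """(X, log_offset_plus_alpha) for fast repeated-draw prediction."""
        self._require_fitted()
        df = panel.copy()
        if design_override is not None:
            df = design_override(df)
        X, _ = self._build_design(df)
        alpha = self.alpha_.reindex(df[self.cluster]).to_numpy()
        off = df[self.denominator].to_numpy(float)
        with np.errstate(divide="ignore"):
            base = np.log(off) + alpha
        return X, base


def fit(panel: pd.DataFrame, spec: ModelSpec) -> FixedEffectsPoisson:
    """Fit a fixed-effects Poisson model described by ``spec``."""
    return spec.to_estimator().fit(panel)


def rate_ratios(model: FixedEffectsPoisson, level: float = 0.95):
    return model.rate_ratios(level=level)


#: (outcome column, denominator column) per major age group
AGE_GROUP_MODELS = {
    "under5": ("deaths_under5", "livebirths"),
    "5_69": ("deaths_5_69", "pop_5_69"),
    "70plus": ("deaths_70plus", "pop_70plus"),
    "overall": ("deaths", "population"),
}


def fit_stratified(panel: pd.DataFrame, base: FixedEffectsPoisson,
                   age_groups: dict | None = None) -> dict:
    """Independent fits per age group (outcome, denominator) pair.

    Empty groups (no rows, or an outcome that is zero everywhere) are
    skipped with a warning rather than raising.
    """
    age_groups = age_groups or AGE_GROUP_MODELS
    out = {}
    for name, (outcome, denom) in age_groups.items():
        est = FixedEffectsPoisson(**{**base.get_params(),
                                     "outcome": outcome,
                                     "denominator": denom})
        try:
            out[name] = est.fit(panel)
        except ValueError as err:
            warnings.warn(f"age group '{name}' skipped: {err}", stacklevel=2)
    return out


def fit_with_dummies(panel: pd.DataFrame, estimator: FixedEffectsPoisson):
    """Cross-check route: explicit municipality-dummy Poisson GLM.

    Uses statsmodels' IRLS Poisson GLM on the same design plus one
    indicator per municipality.  Returns the slope coefficients aligned
    with the conditional-likelihood terms.  Intended for small fixtures.
    """
    import statsmodels.api as sm

    work = FixedEffectsPoisson(**estimator.get_params())
    if work.exposure in _EXPOSURE_CATEGORIES:
        work.exposure_categories_ = _EXPOSURE_CATEGORIES[work.exposure]
    df = work._model_frame(panel)
    if work.time_effects == "year":
        work.year_levels_ = np.sort(df["year"].unique())
    X, names = work._build_design(df)
    dummies = pd.get_dummies(df[work.cluster], dtype=float).to_numpy()
    design = np.column_stack([X, dummies])
    model = sm.GLM(df[work.outcome].to_numpy(float), design,
                   family=sm.families.Poisson(),
                   offset=np.log(df[work.denominator].to_numpy(float)))
    res = model.fit(maxiter=200, tol=1e-12)
    return pd.Series(res.params[:X.shape[1]], index=names, name="coef")
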