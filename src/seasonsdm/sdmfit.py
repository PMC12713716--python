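"""Seasonal suitability models: binomial mixed fits, AIC selection, validation.

Each seasonal subset (winter, spring, June..November) is modelled as a
balanced presence / pseudo-absence classification with a logit-link binomial
model: fixed linear and quadratic effects for every environmental variable and
a random intercept for observation year.  The marginal likelihood integrates
the year intercepts out with Gauss-Hermite quadrature,

    logLik(beta, sigma) = sum_g log integral N(u; 0, sigma^2)
                          prod_{i in g} Bernoulli(y_i; expit(x_i beta + u)) du,

maximised over (beta, log sigma) with an analytic gradient.  AIC counts every
estimated parameter including the random-intercept variance.  Datasets with a
single year level, or fits whose variance collapses to the zero boundary, fall
back to a plain logistic regression (statsmodels GLM) with the fallback flag
set.  Covariates are standardised internally; coefficients are reported on
both scales.

Backward AIC selection respects marginality (a quadratic term is removed
before its linear term and never kept without it).  Discrimination is scored
by AUC (tie-aware Mann-Whitney) and by sensitivity/specificity under three
thresholding rules: a fixed 0.5 cut-off, the observed-score threshold where
sensitivity and specificity are closest, and the largest threshold keeping
sensitivity at 0.95.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import rankdata

from seasonsdm.envio import DEFAULT_SEASON_BINS, EnvStack, extract_env, month_to_bin
from seasonsdm.errors import SingleClassError
from seasonsdm.pabs import SamplerConfig, sample_rs, sample_rsep

logger = logging.getLogger(__name__)

_NON_COVARIATE = {"label", "year", "month", "lon", "lat", "cell_id", "set_id", "method", "subset"}

THRESHOLD_RULES = ("fixed_0.5", "sens_eq_spec", "sens_0.95")


# --------------------------------------------------------------------------
# Fitted model container
# --------------------------------------------------------------------------


@dataclass
class FittedSDM:
    """A fitted (mixed) logistic suitability model.

    ``terms`` maps each retained variable to ``"linear"`` or ``"quadratic"``
    (quadratic always includes the linear term).  ``coef`` holds coefficients
    on the standardised scale, keyed ``Intercept``, ``VAR`` and ``VAR^2``;
    ``means``/``sds`` are the training standardisation constants.  ``sigma2``
    is the year random-intercept variance (0 for the plain-logistic fallback).
    ``aic = 2k - 2 logLik`` with k counting all estimated parameters including
    the variance when present.
    """

    terms: dict[str, str]
    coef: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    sigma2: float
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    converged: bool
    fallback: bool
    se: dict[str, float] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.terms)

    @property
    def raw_coefficients(self) -> dict[str, float]:
        """Coefficients back-transformed to the data (unstandardised) scale."""
        out = {"Intercept": self.coef["Intercept"]}
        for var, kind in self.terms.items():
            mu, s = self.means[var], self.sds[var]
            b1 = self.coef[var]
            b2 = self.coef.get(f"{var}^2", 0.0)
            out[var] = b1 / s - 2 * b2 * mu / s**2
            if kind == "quadratic":
                out[f"{var}^2"] = b2 / s**2
            out["Intercept"] += -b1 * mu / s + b2 * mu**2 / s**2
        return out

    def linear_predictor(self, data: Mapping[str, np.ndarray]) -> np.ndarray:
        """Population-level linear predictor (random intercept at its mean, 0)."""
        first = np.asarray(data[next(iter(self.terms))], dtype=float) if self.terms else None
        eta = np.full(first.shape if first is not None else (), self.coef["Intercept"], dtype=float)
        for var, kind in self.terms.items():
            z = (np.asarray(data[var], dtype=float) - self.means[var]) / self.sds[var]
            eta = eta + self.coef[var] * z
            if kind == "quadratic":
                eta = eta + self.coef[f"{var}^2"] * z * z
        return eta

    def predict(self, data) -> np.ndarray:
        """Population-level occurrence probability for a table or dict of arrays."""
        if isinstance(data, pd.DataFrame):
            if not self.terms:  # intercept-only model: constant probability
                return np.full(len(data), expit(self.coef["Intercept"]))
            data = {v: data[v].to_numpy() for v in self.terms}
        return expit(self.linear_predictor(data))

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coef": self.coef,
            "means": self.means,
            "sds": self.sds,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "fallback": self.fallback,
        }


# --------------------------------------------------------------------------
# Design matrix
# --------------------------------------------------------------------------


def covariate_columns(data: pd.DataFrame) -> list[str]:
    return [c for c in data.columns if c not in _NON_COVARIATE]


def _standardise(data: pd.DataFrame, variables: Sequence[str]):
    means, sds = {}, {}
    for v in variables:
        x = data[v].to_numpy(dtype=float)
        means[v] = float(x.mean())
        s = float(x.std())
        sds[v] = s if s > 0 else 1.0
    return means, sds


def _design(data: pd.DataFrame, terms: Mapping[str, str], means, sds):
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for var, kind in terms.items():
        z = (data[var].to_numpy(dtype=float) - means[var]) / sds[var]
        cols.append(z)
        names.append(var)
        if kind == "quadratic":
            cols.append(z * z)
            names.append(f"{var}^2")
        elif kind != "linear":
            raise ValueError(f"unknown term kind {kind!r} for {var}")
    return np.column_stack(cols), names


# --------------------------------------------------------------------------
# Gauss-Hermite marginal likelihood
# --------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)


def _ghq_nodes(n: int):
    t, w = np.polynomial.hermite.hermgauss(n)
    return t, np.log(w)


def _marginal_loglik_grad(theta, X, y, group_idx, n_groups, t_nodes, log_w):
    """Adaptive-GHQ marginal log-likelihood and gradient wrt (beta, log sigma).

    Quadrature nodes are recentred at each group's posterior mode and rescaled
    by the curvature there (found by a short Newton iteration on the concave
    per-group log-integrand), so the rule stays accurate when large groups make
    the integrand much narrower than the random-effect prior.  The gradient is
    the posterior-weighted score at the nodes; node placement contributes only
    at quadrature-error order because the exact integral does not depend on it.
    """
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    inv_s2 = 1.0 / sigma**2
    xb = X @ beta

    # per-group posterior mode of the random intercept (concave 1-D Newton)
    u = np.zeros(n_groups)
    for _ in range(25):
        mu = expit(xb + u[group_idx])
        score = np.bincount(group_idx, weights=y - mu, minlength=n_groups) - u * inv_s2
        info = np.bincount(group_idx, weights=mu * (1 - mu), minlength=n_groups) + inv_s2
        step = score / info
        u += np.clip(step, -4.0, 4.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(info)  # curvature scale at the mode

    U = u[:, None] + _SQRT2 * tau[:, None] * t_nodes[None, :]  # (G, Q)
    H = xb[:, None] + U[group_idx]  # (n, Q)
    A = y[:, None] * H - np.logaddexp(0.0, H)
    S = np.zeros((n_groups, len(t_nodes)))
    np.add.at(S, group_idx, A)
    # log integrand + adaptive weights: w_q e^{t^2} sqrt(2) tau, prior N(0, sigma^2)
    M = (
        S
        - 0.5 * U**2 * inv_s2
        - np.log(sigma)
        - 0.5 * np.log(2 * np.pi)
        + np.log(_SQRT2 * tau)[:, None]
        + t_nodes[None, :] ** 2
        + log_w[None, :]
    )
    L = logsumexp(M, axis=1)
    ll = float(L.sum())

    P = np.exp(M - L[:, None])  # normalised posterior weights per group
    P_obs = P[group_idx]
    resid = y[:, None] - expit(H)
    w_resid = P_obs * resid
    g_beta = X.T @ w_resid.sum(axis=1)
    # d/d(log sigma) of the prior term at fixed u-nodes: U^2/sigma^2 - 1
    g_log_sigma = float((P * (U**2 * inv_s2 - 1.0)).sum())
    return ll, np.append(g_beta, g_log_sigma)


def _fit_plain_logistic(X, y, names):
    """Plain logistic regression via statsmodels GLM (fallback path)."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        coef = dict(zip(names, res.params))
        se = dict(zip(names, res.bse))
        ll = float(res.llf)
    converged = bool(getattr(res, "converged", True))
    return coef, se, ll, converged


def fit_sdm(
    data: pd.DataFrame,
    terms: Mapping[str, str] | None = None,
    *,
    ghq_points: int = 21,
    variance_boundary: float = 1e-4,
    compute_se: bool = False,
) -> FittedSDM:
    """Fit the binomial year-random-intercept model for one seasonal dataset.

    ``data`` needs a binary ``label`` column, a ``year`` column and one column
    per covariate.  ``terms`` maps variable -> ``"linear"`` | ``"quadratic"``;
    by default every covariate column enters with both terms.  Falls back to a
    plain logistic regression (``fallback=True``) when only one year level is
    present or the variance estimate collapses to the zero boundary.
    """
    y = data["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise SingleClassError("need both presence and absence labels to fit")
    if terms is None:
        terms = {v: "quadratic" for v in covariate_columns(data)}
    terms = dict(terms)
    variables = list(terms)
    means, sds = _standardise(data, variables)
    X, names = _design(data, terms, means, sds)
    n, p = X.shape

    years = data["year"].to_numpy()
    uniq_years, group_idx = np.unique(years, return_inverse=True)
    single_year = len(uniq_years) < 2

    if single_year:
        coef, se, ll, converged = _fit_plain_logistic(X, y, names)
        k = p
        return FittedSDM(terms, coef, means, sds, 0.0, ll, 2 * k - 2 * ll, k, n,
                         converged, fallback=True, se=se)

    t_nodes, log_w = _ghq_nodes(ghq_points)
    n_groups = len(uniq_years)

    def neg(theta):
        ll, g = _marginal_loglik_grad(theta, X, y, group_idx, n_groups, t_nodes, log_w)
        return -ll, -g

    base_rate = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    x0 = np.zeros(p + 1)
    x0[0] = np.log(base_rate / (1 - base_rate))
    x0[-1] = np.log(0.3)
    bounds = [(-50.0, 50.0)] * p + [(np.log(1e-6), np.log(20.0))]
    res = minimize(neg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 500})
    sigma = float(np.exp(res.x[-1]))

    if sigma**2 < variance_boundary:
        # variance at the zero boundary: documented fallback to plain logistic
        coef, se, ll, converged = _fit_plain_logistic(X, y, names)
        k = p
        return FittedSDM(terms, coef, means, sds, 0.0, ll, 2 * k - 2 * ll, k, n,
                         converged, fallback=True, se=se)

    coef = dict(zip(names, res.x[:-1]))
    ll = -float(res.fun)
    k = p + 1  # fixed effects + random-intercept variance
    se: dict[str, float] = {}
    if compute_se:
        se = dict(zip(names, _numeric_se(res.x, X, y, group_idx, n_groups, t_nodes, log_w)))
    if not res.success:
        logger.warning("fit_sdm: optimizer did not report convergence (%s)", res.message)
    return FittedSDM(terms, coef, means, sds, sigma**2, ll, 2 * k - 2 * ll, k, n,
                     bool(res.success), fallback=False, se=se)


def _numeric_se(theta, X, y, group_idx, n_groups, t_nodes, log_w) -> np.ndarray:
    """Fixed-effect standard errors from a finite-difference observed information."""
    p = len(theta)
    h = 1e-5 * np.maximum(1.0, np.abs(theta))
    hess = np.zeros((p, p))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _marginal_loglik_grad(tp, X, y, group_idx, n_groups, t_nodes, log_w)
        _, gm = _marginal_loglik_grad(tm, X, y, group_idx, n_groups, t_nodes, log_w)
        hess[:, j] = (gp - gm) / (2 * h[j])
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(-hess)
        d = np.diag(cov)[:-1]
        return np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        return np.full(p - 1, np.nan)


# --------------------------------------------------------------------------
# Backward AIC selection
# --------------------------------------------------------------------------


def stepwise_aic(
    data: pd.DataFrame,
    full_terms: Mapping[str, str] | None = None,
    **fit_kwargs,
) -> FittedSDM:
    """Backward elimination by AIC under marginality.

    Candidate moves: demote a quadratic variable to linear, or drop a
    linear-only variable.  At each step the move with the lowest AIC is applied
    if it improves on the current AIC; selection stops when no move improves.
    The final AIC is never above the full model's.
    """
    if full_terms is None:
        full_terms = {v: "quadratic" for v in covariate_columns(data)}
    cache: dict[tuple, FittedSDM] = {}

    def key(terms):
        return tuple(sorted(terms.items()))

    def fit(terms):
        k = key(terms)
        if k not in cache:
            cache[k] = fit_sdm(data, terms, **fit_kwargs)
        return cache[k]

    current = fit(dict(full_terms))
    while current.terms:
        candidates = []
        for var, kind in current.terms.items():
            t = dict(current.terms)
            if kind == "quadratic":
                t[var] = "linear"
            else:
                del t[var]
            candidates.append(fit(t))
        best = min(candidates, key=lambda m: m.aic)
        if best.aic < current.aic:
            current = best
        else:
            break
    return current


# --------------------------------------------------------------------------
# Discrimination metrics
# --------------------------------------------------------------------------


def _check_two_classes(labels: np.ndarray):
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise SingleClassError("both classes required")


def auc(scores, labels) -> float:
    """Tie-aware Mann-Whitney AUC: P(random positive outscores a random
    negative), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    r = rankdata(scores, method="average")
    n1 = int((labels == 1).sum())
    n0 = len(labels) - n1
    u = r[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _sens_spec(scores, labels, threshold) -> tuple[float, float]:
    pred = scores >= threshold
    pos = labels == 1
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens, spec


def threshold_metrics(scores, labels, rule: str) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) under one of the three rules.

    ``fixed_0.5``: scores >= 0.5 classified as presence.  ``sens_eq_spec``:
    the observed-score threshold minimising |sens - spec| (ties -> lower
    threshold).  ``sens_0.95``: the largest observed-score threshold with
    sensitivity >= 0.95.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if rule == "fixed_0.5":
        t = 0.5
    elif rule == "sens_eq_spec":
        cand = np.unique(scores)
        gaps = [abs(np.subtract(*_sens_spec(scores, labels, c))) for c in cand]
        t = float(cand[int(np.argmin(gaps))])  # argmin takes the first = lowest
    elif rule == "sens_0.95":
        cand = np.unique(scores)[::-1]  # descending: first hit is the largest
        t = float(cand[-1])
        for c in cand:
            if _sens_spec(scores, labels, c)[0] >= 0.95:
                t = float(c)
                break
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    sens, spec = _sens_spec(scores, labels, t)
    return t, sens, spec


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-fold and aggregate discrimination metrics."""

    records: pd.DataFrame  # columns: fold, rule, auc, threshold, sens, spec

    @property
    def mean_auc(self) -> float:
        return float(self.records.drop_duplicates("fold")["auc"].mean())

    def means(self) -> pd.DataFrame:
        return self.records.groupby("rule")[["auc", "sens", "spec"]].mean().reset_index()


def cross_validate(
    data: pd.DataFrame,
    terms: Mapping[str, str] | None = None,
    k: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> CVReport:
    """Stratified k-fold validation of one model dataset.

    The term set is selected once on the full dataset (backward AIC) unless
    supplied, then refitted on each training split; held-out rows are scored
    with the population-level prediction and summarised by AUC and the three
    thresholding rules.
    """
    from sklearn.model_selection import StratifiedKFold

    y = data["label"].to_numpy()
    _check_two_classes(y)
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise ValueError(f"need at least {k} members of each class for {k}-fold CV")
    if terms is None:
        terms = stepwise_aic(data, **fit_kwargs).terms

    records = []
    for attempt, fold_seed in enumerate((seed, seed + 104729)):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed % 2**31)
        try:
            records = []
            for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
                if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                    raise SingleClassError("single-class fold")
                model = fit_sdm(data.iloc[tr], terms, **fit_kwargs)
                scores = model.predict(data.iloc[te])
                a = auc(scores, y[te])
                for rule in THRESHOLD_RULES:
                    t, sens, spec = threshold_metrics(scores, y[te], rule)
                    records.append(
                        {"fold": fold, "rule": rule, "auc": a, "threshold": t,
                         "sens": sens, "spec": spec}
                    )
            break
        except SingleClassError:
            if attempt == 1:  # re-randomised once already
                raise
    return CVReport(records=pd.DataFrame(records))


# --------------------------------------------------------------------------
# Full factorial design
# --------------------------------------------------------------------------


def build_model_dataset(
    presences: pd.DataFrame,
    pseudo_absences: pd.DataFrame,
    stack: EnvStack,
    variables: Sequence[str],
    subset: str,
    months: Sequence[int],
) -> pd.DataFrame:
    """Label-balanced modelling table for one subset and one replicate set."""
    pres = presences[presences["month"].isin(months)].copy()
    pres["label"] = 1
    absn = pseudo_absences[pseudo_absences["month"].isin(months)].copy()
    pts = pd.concat([pres, absn], ignore_index=True)[
        ["lon", "lat", "year", "month", "cell_id", "label"]
    ]
    out = extract_env(stack, pts, variables)
    out.attrs["subset"] = subset
    if "set_id" in pseudo_absences.columns and len(absn):
        out.attrs["set_id"] = int(absn["set_id"].iloc[0])
    out.attrs["method"] = pseudo_absences.attrs.get("method", "")
    return out


@dataclass
class DesignResult:
    """All fitted sub-models of a methods x replicate-sets x subsets design."""

    models: dict[tuple[str, int, str], FittedSDM]  # (method, set_id, subset)
    datasets: dict[tuple[str, int, str], pd.DataFrame]
    variable_frequency: pd.DataFrame  # method, subset, variable, frequency
    common_variables: dict[tuple[str, str], list[str]]  # (method, subset)
    cv_report: pd.DataFrame | None = None

    @property
    def n_models(self) -> int:
        return len(self.models)

    def models_for(self, method: str, subset: str) -> list[FittedSDM]:
        return [m for (mth, _s, sub), m in self.models.items()
                if mth == method and sub == subset]


def run_design(
    presences: pd.DataFrame,
    stack: EnvStack,
    variables: Sequence[str],
    *,
    methods: Sequence[str] = ("RS", "RSEP"),
    sampler_config: SamplerConfig | None = None,
    season_bins: Mapping[str, Sequence[int]] | None = None,
    run_cv: bool = False,
    cv_folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> DesignResult:
    """Fit the full seasonal design and tabulate retained-variable frequencies.

    For each pseudo-absence method and each of its replicate sets, one
    backward-selected model is fitted per seasonal subset: |methods| x n_sets
    x |season bins| models (80 under the defaults).  The frequency table counts,
    per method and subset, in how many of the replicate sub-models each
    variable survives selection; variables retained in all replicates are the
    subset's common variables.
    """
    season_bins = dict(season_bins or DEFAULT_SEASON_BINS)
    sampler_config = sampler_config or SamplerConfig(seed=seed)

    models: dict[tuple[str, int, str], FittedSDM] = {}
    datasets: dict[tuple[str, int, str], pd.DataFrame] = {}
    cv_rows = []
    for method in methods:
        if method == "RS":
            pa_sets = sample_rs(presences, stack, sampler_config)
        elif method == "RSEP":
            pa_sets = sample_rsep(presences, stack, variables, sampler_config)
        else:
            raise ValueError(f"unknown pseudo-absence method {method!r}")
        for pa in pa_sets:
            set_id = int(pa.attrs["set_id"])
            for subset, months in season_bins.items():
                ds = build_model_dataset(presences, pa, stack, variables, subset, months)
                model = stepwise_aic(ds, **fit_kwargs)
                key = (method, set_id, subset)
                models[key] = model
                datasets[key] = ds
                logger.info("fitted %s set %d subset %s: AIC=%.1f terms=%s",
                            method, set_id, subset, model.aic, sorted(model.terms))
                if run_cv:
                    rep = cross_validate(ds, terms=model.terms, k=cv_folds,
                                         seed=seed + set_id, **fit_kwargs)
                    rec = rep.records.assign(method=method, set_id=set_id, subset=subset)
                    cv_rows.append(rec)

    n_sets = sampler_config.n_sets
    freq_rows = []
    common: dict[tuple[str, str], list[str]] = {}
    for method in methods:
        for subset in season_bins:
            kept_counts = {v: 0 for v in variables}
            for set_id in range(n_sets):
                for v in models[(method, set_id, subset)].terms:
                    kept_counts[v] += 1
            for v, c in kept_counts.items():
                freq_rows.append(
                    {"method": method, "subset": subset, "variable": v, "frequency": c}
                )
            common[(method, subset)] = [v for v, c in kept_counts.items() if c == n_sets]

    cv_report = pd.concat(cv_rows, ignore_index=True) if cv_rows else None
    return DesignResult(
        models=models,
        datasets=datasets,
        variable_frequency=pd.DataFrame(freq_rows),
        common_variables=common,
        cv_report=cv_report,
    )
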