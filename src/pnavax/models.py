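"""Inferential stage: two-level logistic models and companion bivariate tests.

The central model is a random-intercept logistic regression: alter *i* of ego
*j* is vaccinated with probability

.. math::

    \\Pr(y_{ij} = 1 \\mid b_j) = \\mathrm{logit}^{-1}
        (\\mathbf{x}_{ij}^\\top \\beta + b_j),
    \\qquad b_j \\sim \\mathcal{N}(0, \\sigma^2_{ego}),

fitted by maximum likelihood with adaptive Gauss–Hermite quadrature over the
scalar ego intercept (per-group mode finding by Newton's method, quadrature
recentered and rescaled at each mode).  Wald 95% intervals on the log-odds
scale are exponentiated to odds ratios.  The ego-level intraclass correlation
uses the latent-threshold convention
:math:`\\sigma^2 / (\\sigma^2 + \\pi^2/3)`, and variance explained follows the
Nakagawa–Schielzeth marginal/conditional :math:`R^2` for logit models.

A companion population-averaged variant is an ordinary logistic GLM with
ego-clustered (sandwich) standard errors, optionally including the
leave-one-out proportion of vaccinated alters as a predictor in place of the
random intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats
import statsmodels.api as sm

from .errors import ConfigError, SeparationError
from .filtering import ModelFrame

__all__ = [
    "ATTRIBUTE_PREDICTORS",
    "NETWORK_PREDICTORS",
    "FULL_PREDICTORS",
    "MixedFitResult",
    "GlmFitResult",
    "fit_random_intercept_logit",
    "icc_latent",
    "r2_nakagawa",
    "fit_cluster_robust_logit",
    "model_suite",
    "bivariate_suite",
]

#: Level-1 and level-2 attribute predictors (Table-2 ordering).
ATTRIBUTE_PREDICTORS = (
    "alter_sex", "alter_education_z", "alter_single", "alter_age_z",
    "ego_sex", "ego_education_z", "ego_age_z", "ego_employed",
    "ego_vaccinated", "media_online", "media_both",
)

#: Relational/structural predictors: tie intensity, node- and network-level.
NETWORK_PREDICTORS = (
    "intensity", "betweenness_z", "assortativity_z",
    "size_z", "density_z", "components_z",
)

FULL_PREDICTORS = (
    "alter_sex", "alter_education_z", "alter_single", "alter_age_z",
    "intensity", "betweenness_z", "assortativity_z",
    "ego_sex", "ego_education_z", "ego_age_z", "ego_employed",
    "ego_vaccinated", "media_online", "media_both",
    "size_z", "density_z", "components_z",
)

_PI2_3 = np.pi ** 2 / 3.0


@dataclass
class MixedFitResult:
    """Random-intercept logistic fit: coefficients, OR table, variance shares."""

    predictors: tuple
    coef_table: pd.DataFrame        # term, estimate, se, or_, ci_low, ci_high, p
    sigma2_ego: float
    sigma_ego: float
    icc: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    r2_marginal: Optional[float] = None
    r2_conditional: Optional[float] = None
    aic: Optional[float] = None

    @property
    def coefficients(self) -> pd.Series:
        return self.coef_table.set_index("term")["estimate"]

    @property
    def odds_ratios(self) -> pd.Series:
        return self.coef_table.set_index("term")["or_"]


@dataclass
class GlmFitResult:
    """Logistic GLM with ego-clustered robust standard errors."""

    predictors: tuple
    coef_table: pd.DataFrame
    n_obs: int
    n_clusters: int
    loglik: float
    classical_se: pd.Series = field(default_factory=pd.Series)


def _design(df: pd.DataFrame, predictors: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] +
                        [df[p].to_numpy(dtype=float) for p in predictors])
    return X


def _prune_constant(df: pd.DataFrame, predictors: Sequence[str]) -> tuple:
    """Drop predictors without variation (they carry no information and make
    the design singular); returns the usable subset."""
    used, dropped = [], []
    for p in predictors:
        (used if df[p].nunique() > 1 else dropped).append(p)
    if dropped:
        warnings.warn(f"dropping constant predictor(s): {dropped}", stacklevel=3)
    return tuple(used), tuple(dropped)


def _check_separation(df: pd.DataFrame, predictors: Sequence[str],
                      outcome: str) -> None:
    y = df[outcome]
    for p in predictors:
        col = df[p]
        vals = set(col.unique())
        if vals <= {0, 1} and len(vals) == 2:
            tab = pd.crosstab(col, y)
            if tab.shape == (2, 2) and (tab.to_numpy() == 0).any():
                raise SeparationError(p)


def _group_index(df: pd.DataFrame):
    codes, _ = pd.factorize(df["ego_id"], sort=True)
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(codes) > 0])
    return order, codes, starts


def _agq_nll(theta, X, y, starts, codes, n_groups, z_nodes, log_wz):
    """Negative marginal log-likelihood by adaptive Gauss–Hermite quadrature."""
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    eta0 = X @ beta

    # per-group mode of the integrand (Newton; the integrand is log-concave)
    u = np.zeros(n_groups)
    inv_s2 = 1.0 / sigma ** 2
    for _ in range(60):
        eta = eta0 + u[codes]
        p = special.expit(eta)
        g1 = np.add.reduceat(y - p, starts) - u * inv_s2
        g2 = -np.add.reduceat(p * (1 - p), starts) - inv_s2
        step = g1 / g2
        u -= step
        if np.max(np.abs(step)) < 1e-10:
            break
    tau = 1.0 / np.sqrt(-g2)

    # log f(y, u) at shifted/scaled nodes, summed within groups
    logL_k = np.empty((len(z_nodes), n_groups))
    for k, z in enumerate(z_nodes):
        uk = u + np.sqrt(2.0) * tau * z
        eta = eta0 + uk[codes]
        ll_rows = y * eta - np.logaddexp(0.0, eta)
        ll_grp = np.add.reduceat(ll_rows, starts)
        log_prior = -0.5 * uk ** 2 * inv_s2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        logL_k[k] = ll_grp + log_prior
    log_Lj = (np.log(np.sqrt(2.0) * tau)
              + special.logsumexp(logL_k + log_wz[:, None], axis=0))
    return -float(np.sum(log_Lj))


def fit_random_intercept_logit(frame: ModelFrame,
                               predictors: Sequence[str] = FULL_PREDICTORS,
                               outcome: str = "vaccinated",
                               n_quad: int = 15,
                               tol: float = 1e-8) -> MixedFitResult:
    """Maximum-likelihood random-intercept logistic regression.

    Deterministic given the frame and settings: optimization starts from all
    coefficients at zero and the random-intercept SD at one, and proceeds by
    L-BFGS-B on ``(beta, log sigma)``.  Standard errors come from the inverse
    observed information (central-difference Hessian).  Non-convergence is
    flagged on the result, not raised; complete separation of the outcome by
    a binary predictor raises :class:`~pnavax.errors.SeparationError`.
    """
    df = frame.df.sort_values("ego_id", kind="stable").reset_index(drop=True)
    predictors, _ = _prune_constant(df, predictors)
    _check_separation(df, predictors, outcome)
    order, codes, starts = _group_index(df)
    # df is already sorted by ego_id, so order is the identity permutation
    y = df[outcome].to_numpy(dtype=float)
    X = _design(df, predictors)
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ConfigError("random-intercept fit needs >= 2 ego groups")

    z_nodes, w = hermgauss(n_quad)
    log_wz = np.log(w) + z_nodes ** 2

    theta0 = np.zeros(X.shape[1] + 1)  # beta = 0, log sigma = 0 (sigma = 1)
    bounds = [(None, None)] * X.shape[1] + [(-7.0, 3.0)]
    res = optimize.minimize(
        _agq_nll, theta0,
        args=(X, y, starts, codes, n_groups, z_nodes, log_wz),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": tol, "gtol": tol},
    )
    theta = res.x
    loglik = -res.fun
    converged = bool(res.success)

    hess = _numeric_hessian(
        lambda t: _agq_nll(t, X, y, starts, codes, n_groups, z_nodes, log_wz),
        theta)
    try:
        cov = np.linalg.inv(hess)
        if not np.all(np.diag(cov)[:-1] > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
        converged = False
    se = np.sqrt(np.abs(np.diag(cov)))[:X.shape[1]]

    beta = theta[:-1]
    sigma = float(np.exp(theta[-1]))
    terms = ["intercept", *predictors]
    zcrit = stats.norm.ppf(0.975)
    coef_table = pd.DataFrame({
        "term": terms,
        "estimate": beta,
        "se": se,
        "or_": np.exp(beta),
        "ci_low": np.exp(beta - zcrit * se),
        "ci_high": np.exp(beta + zcrit * se),
        "p": 2 * stats.norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf)),
    })

    sigma2 = sigma ** 2
    n_params = X.shape[1] + 1
    fit = MixedFitResult(
        predictors=tuple(predictors),
        coef_table=coef_table,
        sigma2_ego=sigma2,
        sigma_ego=sigma,
        icc=icc_latent(sigma2),
        loglik=loglik,
        n_obs=len(df),
        n_groups=n_groups,
        converged=converged,
        aic=2 * n_params - 2 * loglik,
    )
    fit.r2_marginal, fit.r2_conditional = r2_nakagawa(fit, frame)
    return fit


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = np.empty((n, n))
    steps = eps * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def icc_latent(sigma2_ego: float) -> float:
    """Latent-threshold ICC for logistic models: sigma^2 / (sigma^2 + pi^2/3)."""
    if sigma2_ego < 0:
        raise ValueError(f"variance must be >= 0, got {sigma2_ego}")
    return sigma2_ego / (sigma2_ego + _PI2_3)


def r2_nakagawa(fit: MixedFitResult, frame: ModelFrame) -> tuple:
    """Nakagawa–Schielzeth marginal and conditional R² for the logit model.

    Marginal: variance of the fixed-effect linear predictor over the total
    (fixed + random-intercept + logistic residual pi^2/3); conditional adds
    the random-intercept variance to the numerator.
    """
    df = frame.df
    X = _design(df, fit.predictors)
    beta = fit.coefficients.to_numpy()
    var_f = float(np.var(X @ beta, ddof=1)) if len(df) > 1 else 0.0
    total = var_f + fit.sigma2_ego + _PI2_3
    return var_f / total, (var_f + fit.sigma2_ego) / total


def fit_cluster_robust_logit(frame: ModelFrame,
                             predictors: Sequence[str] = (*FULL_PREDICTORS,
                                                          "loo_prop"),
                             outcome: str = "vaccinated",
                             small_sample_correction: bool = True) -> GlmFitResult:
    """Ordinary logistic GLM with standard errors clustered by ego.

    By default the predictor set appends the leave-one-out vaccinated
    proportion (the fixed-effect stand-in for the missing random intercept).
    The sandwich estimator applies the usual small-sample degrees-of-freedom
    scaling unless disabled.
    """
    df = frame.df
    if df["ego_id"].nunique() < 2:
        raise ConfigError("clustered standard errors need >= 2 ego clusters")
    predictors, _ = _prune_constant(df, predictors)
    _check_separation(df, predictors, outcome)
    y = df[outcome].to_numpy(dtype=float)
    X = _design(df, predictors)
    groups, _ = pd.factorize(df["ego_id"], sort=True)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    base = model.fit()
    robust = model.fit(cov_type="cluster",
                       cov_kwds={"groups": groups,
                                 "use_correction": small_sample_correction})
    terms = ["intercept", *predictors]
    beta = robust.params
    se = robust.bse
    zcrit = stats.norm.ppf(0.975)
    coef_table = pd.DataFrame({
        "term": terms,
        "estimate": beta,
        "se": se,
        "or_": np.exp(beta),
        "ci_low": np.exp(beta - zcrit * se),
        "ci_high": np.exp(beta + zcrit * se),
        "p": 2 * stats.norm.sf(np.abs(beta) / se),
    })
    return GlmFitResult(
        predictors=tuple(predictors),
        coef_table=coef_table,
        n_obs=len(df),
        n_clusters=int(groups.max()) + 1,
        loglik=float(robust.llf),
        classical_se=pd.Series(base.bse, index=terms),
    )


def model_suite(frame: ModelFrame, n_quad: int = 15) -> dict:
    """Fit the four-model comparison suite.

    * ``m1`` — null: intercept plus random ego intercept;
    * ``m2`` — attributes only (alter and ego sociodemographics, media use);
    * ``m3`` — network only (tie intensity, betweenness, assortativity,
      size, density, components);
    * ``m4`` — full model (union of m2 and m3).
    """
    specs = {
        "m1": (),
        "m2": ATTRIBUTE_PREDICTORS,
        "m3": NETWORK_PREDICTORS,
        "m4": FULL_PREDICTORS,
    }
    return {name: fit_random_intercept_logit(frame, predictors=p, n_quad=n_quad)
            for name, p in specs.items()}


def _chi2_or_exact(table: pd.DataFrame, rng_seed: int = 20230913) -> dict:
    """Pearson chi-square with an exact/permutation fallback for sparse tables."""
    arr = table.to_numpy()
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    note = ""
    if (expected < 5).any():
        if arr.shape == (2, 2):
            _, p = stats.fisher_exact(arr)
            note = "fisher_exact"
        else:
            # Monte-Carlo exact test: permute one margin, seeded for determinism
            rng = np.random.default_rng(rng_seed)
            rows = np.repeat(np.arange(arr.shape[0]), arr.sum(axis=1))
            cols = np.repeat(np.arange(arr.shape[1]), arr.sum(axis=0))
            hits = 0
            n_perm = 2000
            for _ in range(n_perm):
                perm = rng.permutation(cols)
                sim = np.zeros_like(arr)
                np.add.at(sim, (rows, perm), 1)
                sim_chi2 = ((sim - expected) ** 2 / expected).sum()
                if sim_chi2 >= chi2 - 1e-12:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
            note = "monte_carlo_exact"
    return {"statistic": chi2, "df": dof, "p": p, "note": note}


def bivariate_suite(frame: ModelFrame) -> pd.DataFrame:
    """Routine companion tests around the main models.

    Chi-square tests of alter vaccination against ego vaccination and ego
    media use; a test of ego vaccination against media use at the ego level;
    two-sided pooled-variance t tests of the (unstandardized) assortativity
    score by alter and by ego vaccination; and a chi-square of assortativity
    quartiles against the ego media-by-vaccination grouping.  Sparse tables
    fall back to exact tests (logged in the ``note`` column).
    """
    df = frame.df
    rows = []

    def add(name, res, method="chi2"):
        rows.append({"test": name, "method": res.get("method", method),
                     "statistic": res["statistic"], "df": res["df"],
                     "p": res["p"], "note": res.get("note", "")})

    add("alter_vacc_by_ego_vacc",
        _chi2_or_exact(pd.crosstab(df["vaccinated"], df["ego_vaccinated"])))
    add("alter_vacc_by_ego_media",
        _chi2_or_exact(pd.crosstab(df["vaccinated"], df["media_category"])))
    egos = df.drop_duplicates("ego_id")
    add("ego_vacc_by_ego_media",
        _chi2_or_exact(pd.crosstab(egos["ego_vaccinated"], egos["media_category"])))

    for name, col in (("assort_by_alter_vacc", "vaccinated"),
                      ("assort_by_ego_vacc", "ego_vaccinated")):
        a = df.loc[df[col] == 0, "assortativity"]
        b = df.loc[df[col] == 1, "assortativity"]
        t, p = stats.ttest_ind(a, b, equal_var=True)
        add(name, {"statistic": t, "df": len(a) + len(b) - 2, "p": p},
            method="t_test")

    quartile = pd.qcut(df["assortativity"], 4, labels=False, duplicates="drop")
    group = df["media_category"].astype(str) + ":" + df["ego_vaccinated"].astype(str)
    add("assort_quartile_by_media_vacc",
        _chi2_or_exact(pd.crosstab(quartile, group)))

    return pd.DataFrame(rows)
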