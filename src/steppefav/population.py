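"""Inferential models for favourability trends and bird abundance.

Three models mirror the analysis chain for the study system:

* ``favourability_trend_glm`` — a Gaussian GLM (OLS) of cell favourability on
  standardized year, protection level and their interaction, summarized with
  a type III ANOVA under sum-to-zero contrasts;
* ``abundance_glm`` — a Poisson GLM (log link) of males per census point on
  protection level, with a likelihood-ratio test of the protection effect;
* ``fit_poisson_glmm`` — a Poisson GLMM with a Gaussian random intercept per
  census point, fitted by adaptive Gauss-Hermite quadrature, for the
  trend/favourability/conspecific-attraction model of annual reserve counts.

The conspecific-attraction covariate (``neighbouring_males``) is the number
of males counted at *other* points within 1.7 km in the same year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .errors import NonConvergenceError, SchemaError

# ---------------------------------------------------------------------------
# favourability ~ year x protection (Gaussian GLM, type III ANOVA)


def _sum_contrasts(levels: list[str], values: pd.Series) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k-1 columns, last level = -1 row."""
    k = len(levels)
    cols = np.zeros((len(values), k - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (values == lev).astype(float)
    cols[(values == levels[-1]).to_numpy()] = -1.0
    return cols


def favourability_trend_glm(
    panel: pd.DataFrame,
    response: str = "favourability",
    year_col: str = "year",
    protection_col: str = "protection",
) -> tuple[pd.Series, pd.DataFrame]:
    """OLS of favourability on standardized year, protection, interaction.

    Type III sums of squares: each term's SS compares the full model with the
    model deleting that term's columns while retaining all others (including
    the interaction), under sum-to-zero contrasts — so main effects are tested
    at the average of the other factor. Returns (estimates, anova table). The
    ANOVA table carries SS, df, F, p and the partial R^2
    ``SS_term / (SS_term + SS_residual)``.
    """
    levels = sorted(panel[protection_col].unique())
    if len(levels) < 2:
        raise SchemaError("trend model needs at least two protection levels")
    years = panel[year_col].astype(float)
    if years.nunique() < 2:
        raise SchemaError("trend model needs at least two years")
    zyear = ((years - years.mean()) / years.std(ddof=1)).to_numpy()
    prot = _sum_contrasts(levels, panel[protection_col])
    inter = prot * zyear[:, None]
    y = panel[response].to_numpy(dtype=float)
    n = len(y)

    blocks = {
        "year": zyear[:, None],
        "protection": prot,
        "year:protection": inter,
    }
    names = ["intercept", "year"] + [
        f"protection[{lev}]" for lev in levels[:-1]
    ] + [f"year:protection[{lev}]" for lev in levels[:-1]]
    X_full = np.column_stack([np.ones(n)] + list(blocks.values()))

    def rss(X: np.ndarray) -> float:
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r), coef

    rss_full, coef_full = rss(X_full)
    df_res = n - X_full.shape[1]
    rows = []
    for term, block in blocks.items():
        others = [b for t, b in blocks.items() if t != term]
        X_red = np.column_stack([np.ones(n)] + others)
        rss_red, _ = rss(X_red)
        ss = rss_red - rss_full
        df = block.shape[1]
        f_stat = (ss / df) / (rss_full / df_res)
        p = stats.f.sf(f_stat, df, df_res)
        rows.append(
            {
                "term": term,
                "sum_sq": ss,
                "df": df,
                "F": f_stat,
                "p": p,
                "partial_r2": ss / (ss + rss_full),
            }
        )
    rows.append(
        {"term": "residual", "sum_sq": rss_full, "df": df_res, "F": np.nan,
         "p": np.nan, "partial_r2": np.nan}
    )
    anova = pd.DataFrame(rows).set_index("term")
    estimates = pd.Series(coef_full, index=names)
    return estimates, anova


# ---------------------------------------------------------------------------
# abundance ~ protection (Poisson GLM)


@dataclass
class AbundanceFit:
    """Poisson GLM of counts on a protection factor."""

    group_means: pd.Series  # fitted = observed means per level (canonical link)
    params: pd.Series  # log-scale coefficients, reference = first level
    llf: float
    llf_null: float
    lr_chi2: float
    lr_df: int
    lr_p: float


def abundance_glm(counts, protection) -> AbundanceFit:
    """Poisson GLM (log link) of males per point on protection level.

    With the canonical link and a saturated factor, fitted level means equal
    the observed level means. The overall protection effect is tested by a
    likelihood-ratio chi-square against the intercept-only model with
    ``levels - 1`` degrees of freedom. An all-zero level is flagged with a
    boundary warning (its log-mean is -inf).
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise SchemaError("counts must be nonnegative integers")
    prot = pd.Series(np.asarray(protection, dtype=object))
    levels = sorted(prot.unique())
    if len(levels) < 2:
        raise SchemaError("abundance model needs at least two protection levels")
    means = pd.Series({lev: y[(prot == lev).to_numpy()].mean() for lev in levels})
    if (means == 0).any():
        import warnings

        warnings.warn(
            f"level(s) {list(means.index[means == 0])} have zero counts; fitted "
            "mean at the boundary",
            stacklevel=2,
        )
    dummies = np.column_stack(
        [np.ones(len(y))] + [(prot == lev).to_numpy(float) for lev in levels[1:]]
    )
    res = sm.GLM(y, dummies, family=sm.families.Poisson()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Poisson()).fit()
    lr = 2 * (res.llf - null.llf)
    df = len(levels) - 1
    names = [f"log_mean[{levels[0]}]"] + [f"log_ratio[{lev}]" for lev in levels[1:]]
    return AbundanceFit(
        group_means=means,
        params=pd.Series(np.asarray(res.params), index=names),
        llf=float(res.llf),
        llf_null=float(null.llf),
        lr_chi2=float(lr),
        lr_df=df,
        lr_p=float(stats.chi2.sf(lr, df)),
    )


# ---------------------------------------------------------------------------
# conspecific attraction covariate


def neighbouring_males(census: pd.DataFrame, radius: float = 1700.0) -> pd.Series:
    """Males counted at *other* points within ``radius`` in the same year.

    Euclidean distances in the projected CRS; points exactly at the radius
    are included. Raises on duplicate (point_id, year) records.
    """
    required = {"point_id", "x", "y", "year", "males"}
    missing = required - set(census.columns)
    if missing:
        raise SchemaError(f"census table missing columns: {sorted(missing)}")
    if census.duplicated(["point_id", "year"]).any():
        raise SchemaError("duplicate point_id within a year")
    out = pd.Series(0.0, index=census.index)
    for _, grp in census.groupby("year"):
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        males = grp["males"].to_numpy(dtype=float)
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        within = d2 <= radius**2
        np.fill_diagonal(within, False)
        out.loc[grp.index] = within @ males
    return out


# ---------------------------------------------------------------------------
# Poisson random-intercept GLMM via adaptive Gauss-Hermite quadrature


@dataclass
class GlmmFit:
    """A fitted Poisson GLMM with one Gaussian random intercept per group."""

    variables: list[str]
    params: pd.Series  # ["intercept", *variables]
    sigma: float  # random-intercept standard deviation
    llf: float
    n_groups: int
    n_obs: int
    n_quad: int
    cov_params: pd.DataFrame | None = None
    dispersion: float | None = None  # Pearson chi2 / df
    boundary: bool = False  # sigma estimated at the 0 boundary
    term_tests: pd.DataFrame | None = None  # per-term LR chi2 / p

    @property
    def n_params(self) -> int:
        return len(self.params) + 1  # + sigma

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.cov_params is None:
            raise SchemaError("fit carries no covariance matrix")
        idx = list(self.params.index)
        se = np.sqrt(np.diag(self.cov_params.loc[idx, idx].to_numpy()))
        z = stats.norm.ppf(1 - alpha / 2)
        est = self.params.to_numpy()
        return pd.DataFrame(
            {"lower": est - z * se, "upper": est + z * se}, index=idx
        )


class _GroupData:
    """Per-group sufficient statistics for the random-intercept likelihood.

    Because the random effect enters every observation of a group additively
    on the log scale, the group's integrand depends on u only through
    ``Y_g = sum(y)`` and ``E_g(beta) = sum(exp(eta))``; per-group quantities
    are therefore scalars and everything vectorizes across groups.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.X = X[order]
        g = groups[order]
        self.starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
        self.n_groups = len(self.starts)
        self.const = -gammaln(self.y + 1).sum()
        self.Y = np.add.reduceat(self.y, self.starts)

    def group_sums(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts)


def _glmm_loglik(
    theta: np.ndarray, data: _GroupData, nodes: np.ndarray, weights: np.ndarray
) -> float:
    beta, sigma = theta[:-1], theta[-1]
    eta = data.X @ beta
    if eta.max() > 500:
        return -np.inf
    E = data.group_sums(np.exp(eta))
    Y = data.Y
    yeta = data.group_sums(data.y * eta)

    # mode of h(u) = sigma*Y*u - E*exp(sigma*u) - u^2/2 per group (Newton,
    # h' monotone decreasing so this is safe)
    u = np.zeros(data.n_groups)
    for _ in range(50):
        expo = np.exp(np.clip(sigma * u, -500, 500))
        f = sigma * Y - sigma * E * expo - u
        fp = -(sigma**2) * E * expo - 1.0
        step = f / fp
        u -= step
        if np.max(np.abs(step)) < 1e-12:
            break
    expo = np.exp(sigma * u)
    s = 1.0 / np.sqrt(sigma**2 * E * expo + 1.0)

    # adaptive GH: integral = sqrt(2)*s * sum_k w_k exp(h(u + sqrt(2) s x_k) + x_k^2)
    pts = u[:, None] + np.sqrt(2.0) * s[:, None] * nodes[None, :]
    h = (
        sigma * Y[:, None] * pts
        - E[:, None] * np.exp(np.clip(sigma * pts, -500, 500))
        - 0.5 * pts**2
    )
    log_integrand = h + nodes[None, :] ** 2 + np.log(weights)[None, :]
    log_L = (
        0.5 * np.log(2.0)
        + np.log(s)
        + logsumexp(log_integrand, axis=1)
        - 0.5 * np.log(2.0 * np.pi)
    )
    return float(log_L.sum() + yeta.sum() + data.const)


def glmm_loglik_bruteforce(
    counts, covariates: pd.DataFrame, group_ids, params, sigma,
    n_grid: int = 100_000, span: float = 12.0,
) -> float:
    """Marginal log-likelihood by dense trapezoid integration (test oracle)."""
    y = np.asarray(counts, dtype=float)
    X = np.column_stack([np.ones(len(y))] + [covariates[c].to_numpy(float) for c in covariates])
    beta = np.asarray(params, dtype=float)
    eta = X @ beta
    u = np.linspace(-span, span, n_grid)
    total = 0.0
    for g in pd.unique(np.asarray(group_ids)):
        mask = np.asarray(group_ids) == g
        ll_u = (
            (y[mask, None] * (eta[mask, None] + sigma * u[None, :])).sum(0)
            - np.exp(eta[mask, None] + sigma * u[None, :]).sum(0)
            - gammaln(y[mask] + 1).sum()
        )
        dens = np.exp(ll_u) * stats.norm.pdf(u)
        total += np.log(np.trapezoid(dens, u))
    return float(total)


def fit_poisson_glmm(
    counts,
    covariates: pd.DataFrame,
    group_ids,
    n_quad: int = 15,
    term_tests: bool = True,
    _start: np.ndarray | None = None,
) -> GlmmFit:
    """Poisson log-link GLMM with a single Gaussian random intercept.

    The marginal likelihood integrates the random intercept out by adaptive
    Gauss-Hermite quadrature (default 15 nodes, centred and scaled at each
    group's conditional mode). Fixed effects and the random-intercept SD are
    maximized jointly (L-BFGS-B, sigma bounded at 0); standard errors come
    from a central finite-difference Hessian. A sigma estimate at the 0
    boundary is flagged but the fit is still returned. ``term_tests`` adds a
    likelihood-ratio chi-square per covariate (model refitted without the
    term). The reported dispersion is Pearson chi-square over residual df
    using conditional means at the empirical-Bayes modes.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise SchemaError("counts must be nonnegative integers")
    variables = list(covariates.columns)
    X = np.column_stack(
        [np.ones(len(y))] + [covariates[v].to_numpy(dtype=float) for v in variables]
    )
    groups, group_idx = np.unique(np.asarray(group_ids), return_inverse=True)
    if len(groups) < 2:
        raise SchemaError("GLMM needs at least two groups")
    if len(y) / len(groups) < 2:
        raise SchemaError("GLMM needs at least two observations per group on average")
    data = _GroupData(y, X, group_idx)
    nodes, weights = hermgauss(n_quad)

    if _start is None:
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        _start = np.r_[np.asarray(glm.params), 0.3]
    bounds = [(None, None)] * X.shape[1] + [(0.0, 20.0)]

    def neg(theta: np.ndarray) -> float:
        return -_glmm_loglik(theta, data, nodes, weights)

    res = optimize.minimize(
        neg, _start, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-2:
        raise NonConvergenceError(
            f"GLMM did not converge: {res.message}; |grad| = {np.abs(res.jac).max():.3g}"
        )
    theta = res.x
    beta, sigma = theta[:-1], theta[-1]
    llf = -res.fun
    boundary = sigma < 1e-4

    index = ["intercept"] + variables
    cov = _fd_covariance(neg, theta, index, boundary)

    # empirical-Bayes conditional means for the dispersion statistic
    eta = data.X @ beta
    E = data.group_sums(np.exp(eta))
    u = np.zeros(data.n_groups)
    for _ in range(50):
        expo = np.exp(np.clip(sigma * u, -500, 500))
        f = sigma * data.Y - sigma * E * expo - u
        u -= f / (-(sigma**2) * E * expo - 1.0)
    u_per_row = np.repeat(u, np.diff(np.r_[data.starts, len(data.y)]))
    mu = np.exp(eta + sigma * u_per_row)
    pearson = ((data.y - mu) ** 2 / mu).sum()
    df_res = len(y) - (X.shape[1] + 1)
    dispersion = float(pearson / df_res)

    tests = None
    if term_tests and variables:
        rows = []
        for v in variables:
            reduced = fit_poisson_glmm(
                counts, covariates.drop(columns=[v]), group_ids,
                n_quad=n_quad, term_tests=False,
            )
            chi2 = max(0.0, 2 * (llf - reduced.llf))
            rows.append({"term": v, "lr_chi2": chi2, "df": 1,
                         "p": stats.chi2.sf(chi2, 1)})
        tests = pd.DataFrame(rows).set_index("term")

    return GlmmFit(
        variables=variables,
        params=pd.Series(beta, index=index),
        sigma=float(sigma),
        llf=float(llf),
        n_groups=len(groups),
        n_obs=len(y),
        n_quad=n_quad,
        cov_params=cov,
        dispersion=dispersion,
        boundary=bool(boundary),
        term_tests=tests,
    )


def _fd_covariance(neg, theta: np.ndarray, index: list[str], boundary: bool):
    """Covariance of (beta, sigma) from a central finite-difference Hessian.

    At a sigma boundary only the beta block is inverted (the sigma row/col is
    reported as NaN)."""
    k = len(theta)
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    if boundary:
        h[-1] = 0.0
    hess = np.zeros((k, k))
    f0 = neg(theta)
    active = [i for i in range(k) if h[i] > 0]
    for ai, i in enumerate(active):
        for j in active[ai:]:
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            if i == j:
                val = (neg(theta + ei) - 2 * f0 + neg(theta - ei)) / h[i] ** 2
            else:
                val = (
                    neg(theta + ei + ej) - neg(theta + ei - ej)
                    - neg(theta - ei + ej) + neg(theta - ei - ej)
                ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    names = index + ["sigma"]
    cov = np.full((k, k), np.nan)
    sub = np.ix_(active, active)
    try:
        cov[sub] = np.linalg.inv(hess[sub])
    except np.linalg.LinAlgError:
        pass
    return pd.DataFrame(cov, index=names, columns=names)


def lr_term_test(full, reduced) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Works on any pair of fits exposing ``llf`` and ``variables`` (e.g.
    :class:`GlmmFit` or a logistic fit). Returns (chi2, df, p).
    """
    for fit in (full, reduced):
        if not hasattr(fit, "llf") or not hasattr(fit, "variables"):
            raise SchemaError("fits must expose llf and variables")
    if not set(reduced.variables) <= set(full.variables):
        raise SchemaError("models are not nested")
    df = len(full.variables) - len(reduced.variables)
    if df == 0 and set(reduced.variables) == set(full.variables):
        return 0.0, 0, 1.0
    if df <= 0:
        raise SchemaError("models are not nested")
    chi2 = max(0.0, 2 * (full.llf - reduced.llf))
    return float(chi2), df, float(stats.chi2.sf(chi2, df))
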