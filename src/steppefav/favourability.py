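"""Prevalence-corrected favourability modelling of species occurrence.

The occurrence model is an ordinary binomial GLM (logit link) on standardized
buffer land-use features, selected by bidirectional stepwise AIC starting from
the full model. Its predicted probability P depends on sample prevalence,
which makes raw probabilities incomparable across samples or years; the
favourability transform removes that dependence::

    F = (P / (1 - P)) / (n1/n0 + P / (1 - P))

where ``n1`` and ``n0`` are the numbers of presences and absences in the
training sample. Equivalently, F is the logistic function evaluated at the
model's linear predictor with the intercept shifted by ``-ln(n1/n0)``; both
routes are implemented and must agree to 1e-12. F equals 0.5 exactly where P
equals the sample prevalence, so F > 0.5 marks conditions more favourable
than the sample average regardless of how rare the species is.

Diagnostics follow standard practice for presence/absence models: AUC as the
Mann-Whitney concordance probability, Dunn-Smyth randomized quantile
residuals, and a permutation Moran's I test for residual spatial
autocorrelation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

from .errors import (
    DegenerateVariableError,
    SchemaError,
    SeparationError,
    UndefinedAUCError,
)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Per-variable training means and standard deviations (sample, ddof=1)."""

    means: pd.Series
    sds: pd.Series

    def transform(
        self, features: pd.DataFrame, columns: list[str] | None = None
    ) -> pd.DataFrame:
        cols = list(self.means.index) if columns is None else list(columns)
        unknown = set(cols) - set(self.means.index)
        if unknown:
            raise SchemaError(f"no training statistics for: {sorted(unknown)}")
        missing = set(cols) - set(features.columns)
        if missing:
            raise SchemaError(f"features missing standardized columns: {sorted(missing)}")
        return (features[cols] - self.means[cols]) / self.sds[cols]

    def to_dict(self) -> dict:
        return {"means": self.means.to_dict(), "sds": self.sds.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(means=pd.Series(d["means"]), sds=pd.Series(d["sds"]))


def standardize(
    features: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, Standardizer]:
    """Centre and scale candidate variables to mean 0, sd 1 (sample sd).

    Raises :class:`DegenerateVariableError` naming any zero-variance column.
    """
    if columns is None:
        columns = list(features.columns)
    sub = features[columns].astype(float)
    sds = sub.std(ddof=1)
    dead = sds.index[(sds == 0) | sds.isna()].tolist()
    if dead:
        raise DegenerateVariableError(
            f"zero-variance candidate variable(s): {dead}"
        )
    std = Standardizer(means=sub.mean(), sds=sds)
    out = features.copy()
    out[columns] = std.transform(sub)
    return out, std


def vif(features: pd.DataFrame, limit: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from the OLS regression of variable j on all other candidates
    (with intercept). Perfect collinearity is reported as infinite VIF and
    flagged, never raised. Returns a frame with columns ``vif`` and
    ``flagged`` (VIF >= limit).
    """
    cols = list(features.columns)
    if len(cols) < 2:
        raise SchemaError("VIF needs at least two candidate variables")
    X = features[cols].to_numpy(dtype=float)
    n = X.shape[0]
    if n <= len(cols):
        raise SchemaError("VIF needs more observations than variables")
    out = {}
    for j, col in enumerate(cols):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    table = pd.DataFrame({"vif": pd.Series(out)})
    table["flagged"] = table["vif"] >= limit
    return table


# ---------------------------------------------------------------------------
# logistic fit


@dataclass
class LogisticFit:
    """A fitted binomial GLM with the bookkeeping downstream stages need."""

    variables: list[str]  # slope variable names, intercept excluded
    params: pd.Series  # index: ["intercept", *variables]
    llf: float
    aic: float
    fitted: np.ndarray  # fitted probabilities per training row
    n1: int
    n0: int
    cov_params: pd.DataFrame | None = None

    @property
    def n_obs(self) -> int:
        return self.n1 + self.n0

    def linear_predictor(self, features: pd.DataFrame) -> np.ndarray:
        missing = set(self.variables) - set(features.columns)
        if missing:
            raise SchemaError(f"features missing model variables: {sorted(missing)}")
        eta = np.full(len(features), self.params["intercept"], dtype=float)
        for v in self.variables:
            eta += self.params[v] * features[v].to_numpy(dtype=float)
        return eta

    def predict_probability(self, features: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(features))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.cov_params is None:
            raise SchemaError("fit carries no covariance matrix")
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        z = stats.norm.ppf(1 - alpha / 2)
        est = self.params.to_numpy()
        return pd.DataFrame(
            {"lower": est - z * se, "upper": est + z * se}, index=self.params.index
        )


def fit_logistic(response, design: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood binomial GLM (logit link) via IRLS.

    ``design`` holds the slope columns only; an intercept is always added.
    Raises :class:`SeparationError` on (quasi-)complete separation and
    :class:`SchemaError` on rank-deficient designs.
    """
    y = np.asarray(response, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise SchemaError("response must be binary 0/1")
    variables = list(design.columns)
    X = np.column_stack([np.ones(len(y))] + [design[v].to_numpy(dtype=float) for v in variables])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SchemaError("design matrix is rank deficient")
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise SeparationError("response contains a single class")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(maxiter=200, tol=1e-10)
    except PerfectSeparationWarning as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from exc
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    fitted = expit(X @ params)
    if not res.converged or np.abs(params).max() > 1e3:
        raise SeparationError(
            "logistic fit did not converge (likely complete separation); "
            f"max |coef| = {np.abs(params).max():.3g}"
        )
    index = ["intercept"] + variables
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=index, columns=index)
    return LogisticFit(
        variables=variables,
        params=pd.Series(params, index=index),
        llf=float(res.llf),
        aic=float(-2 * res.llf + 2 * len(params)),
        fitted=fitted,
        n1=n1,
        n0=n0,
        cov_params=cov,
    )


def stepwise_aic(
    response, candidates: pd.DataFrame, verbose: bool = False
) -> LogisticFit:
    """Bidirectional stepwise AIC selection starting from the full model.

    At every step all single-variable drops and additions are scored; the
    move with the lowest AIC is taken; the search stops when no move improves
    on the current AIC. Ties are broken towards fewer parameters, then by
    variable order. The intercept is always retained. An empty candidate set
    yields the intercept-only model. If the full starting model is separated,
    the search restarts forward from the intercept-only model instead.
    """
    all_vars = list(candidates.columns)
    current = list(all_vars)
    cache: dict[tuple, LogisticFit] = {}

    def fit_subset(subset: tuple) -> LogisticFit:
        if subset not in cache:
            cache[subset] = fit_logistic(response, candidates[list(subset)])
        return cache[subset]

    try:
        best = fit_subset(tuple(current))
    except SeparationError:
        current = []
        best = fit_subset(())
    while True:
        moves: list[tuple[float, int, tuple]] = []
        for v in current:  # drops
            subset = tuple(u for u in current if u != v)
            try:
                f = fit_subset(subset)
            except SeparationError:
                continue
            moves.append((f.aic, len(subset), subset))
        for v in all_vars:  # additions
            if v in current:
                continue
            subset = tuple(current) + (v,)
            subset = tuple(u for u in all_vars if u in subset)  # canonical order
            try:
                f = fit_subset(subset)
            except SeparationError:
                continue
            moves.append((f.aic, len(subset), subset))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aic, _, best_subset = moves[0]
        if best_aic < best.aic - 1e-10:
            current = list(best_subset)
            best = fit_subset(best_subset)
            if verbose:
                print(f"step -> {current} AIC={best.aic:.3f}")
        else:
            break
    return best


# ---------------------------------------------------------------------------
# the favourability transform


def favourability_transform(P, n1: int, n0: int):
    """Prevalence-corrected favourability of predicted probabilities.

    F = odds(P) / (n1/n0 + odds(P)); F in [0, 1], F(P=1) := 1 by continuity,
    monotone increasing in P, and F = 0.5 exactly at P = n1/(n1+n0).
    """
    if n1 <= 0 or n0 <= 0:
        raise ValueError("presence and absence counts must be positive")
    p = np.asarray(P, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    ratio = n1 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = p / (1.0 - p)
        f = np.where(p >= 1.0, 1.0, odds / (ratio + odds))
    return f if f.ndim else float(f)


@dataclass
class FavourabilityModel:
    """A logistic fit repackaged on the favourability scale.

    The favourability intercept is ``b0F = b0 - ln(n1/n0)``; slopes are those
    of the logistic fit; evaluating the logistic function at the shifted
    linear predictor reproduces ``favourability_transform`` of the fitted
    probabilities exactly.
    """

    fit: LogisticFit
    standardizer: Standardizer
    b0f: float
    auc: float | None = None
    moran_i: float | None = None
    moran_p: float | None = None
    r2_deviance: float | None = None
    r2_nagelkerke: float | None = None

    def favourability_linear_predictor(self, std_features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(std_features), self.b0f, dtype=float)
        for v in self.fit.variables:
            eta += self.fit.params[v] * std_features[v].to_numpy(dtype=float)
        return eta

    def predict_favourability(self, raw_features: pd.DataFrame) -> np.ndarray:
        """Favourability for features on the training (raw proportion) scale."""
        std = self.standardizer.transform(raw_features, columns=self.fit.variables)
        return expit(self.favourability_linear_predictor(std))

    def to_json(self, path=None) -> str:
        payload = {
            "variables": self.fit.variables,
            "params": self.fit.params.to_dict(),
            "n1": self.fit.n1,
            "n0": self.fit.n0,
            "llf": self.fit.llf,
            "aic": self.fit.aic,
            "b0f": self.b0f,
            "standardizer": self.standardizer.to_dict(),
            "diagnostics": {
                "auc": self.auc,
                "moran_i": self.moran_i,
                "moran_p": self.moran_p,
                "r2_deviance": self.r2_deviance,
                "r2_nagelkerke": self.r2_nagelkerke,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FavourabilityModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        params = pd.Series(payload["params"])
        fit = LogisticFit(
            variables=payload["variables"],
            params=params,
            llf=payload["llf"],
            aic=payload["aic"],
            fitted=np.array([]),
            n1=payload["n1"],
            n0=payload["n0"],
        )
        diag = payload.get("diagnostics", {})
        return cls(
            fit=fit,
            standardizer=Standardizer.from_dict(payload["standardizer"]),
            b0f=payload["b0f"],
            auc=diag.get("auc"),
            moran_i=diag.get("moran_i"),
            moran_p=diag.get("moran_p"),
            r2_deviance=diag.get("r2_deviance"),
            r2_nagelkerke=diag.get("r2_nagelkerke"),
        )


def build_favourability_model(
    fit: LogisticFit, standardizer: Standardizer
) -> FavourabilityModel:
    """Shift the fitted intercept by -ln(n1/n0) onto the favourability scale.

    The two computation routes (ratio transform of P vs logistic at the
    shifted predictor) must agree to 1e-12 on the training rows; this is
    asserted here so a serialized model is internally consistent by
    construction.
    """
    b0f = float(fit.params["intercept"] - np.log(fit.n1 / fit.n0))
    y = logit(fit.fitted)
    route_a = favourability_transform(fit.fitted, fit.n1, fit.n0)
    route_b = expit(y - np.log(fit.n1 / fit.n0))
    if np.max(np.abs(route_a - route_b)) > 1e-12:
        raise AssertionError("favourability identity violated beyond 1e-12")
    n = fit.n_obs
    # explained deviance and Nagelkerke R^2; neither is the only convention,
    # so both are reported
    p_bar = fit.n1 / n
    ll_null = fit.n1 * np.log(p_bar) + fit.n0 * np.log(1 - p_bar)
    r2_dev = 1.0 - fit.llf / ll_null
    r2_nag = (1 - np.exp(2 * (ll_null - fit.llf) / n)) / (1 - np.exp(2 * ll_null / n))
    return FavourabilityModel(
        fit=fit,
        standardizer=standardizer,
        b0f=b0f,
        r2_deviance=float(r2_dev),
        r2_nagelkerke=float(r2_nag),
    )


# ---------------------------------------------------------------------------
# diagnostics


def auc(scores, response) -> float:
    """AUC as the Mann-Whitney probability P(score_1 > score_0) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(response)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("AUC undefined: one response class absent")
    ranks = stats.rankdata(s)  # midranks handle ties
    r_pos = ranks[y == 1].sum()
    n1, n0 = len(pos), len(neg)
    return float((r_pos - n1 * (n1 + 1) / 2) / (n1 * n0))


def quantile_residuals(fitted, response, rng_seed: int = 0) -> np.ndarray:
    """Dunn-Smyth randomized quantile residuals for Bernoulli responses.

    For observation i, a uniform is drawn on the CDF interval the observed
    outcome occupies — (0, 1-P_i) for y=0 and (1-P_i, 1) for y=1 — and mapped
    through the standard-normal quantile function. Normal iid under a
    correctly specified model; deterministic given the seed.
    """
    p = np.asarray(fitted, dtype=float)
    y = np.asarray(response)
    rng = np.random.default_rng(rng_seed)
    u = rng.uniform(size=len(p))
    lower = np.where(y == 1, 1.0 - p, 0.0)
    upper = np.where(y == 1, 1.0, 1.0 - p)
    draws = lower + u * (upper - lower)
    draws = np.clip(draws, 1e-12, 1 - 1e-12)
    return stats.norm.ppf(draws)


def morans_test(
    values,
    coords,
    n_permutations: int = 999,
    rng_seed: int = 0,
    weights: str = "inverse_distance",
    k_neighbours: int = 8,
) -> tuple[float, float]:
    """Moran's I with a two-sided permutation test.

    Weights are row-standardized inverse Euclidean distances with a zero
    diagonal by default (``weights='knn'`` uses binary k-nearest-neighbour
    weights instead). The permutation p-value is
    ``(1 + #{|I_perm - E[I]| >= |I_obs - E[I]|}) / (n_permutations + 1)`` with
    the null expectation ``E[I] = -1/(n-1)``.
    """
    z = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 10:
        raise SchemaError("Moran's test needs at least 10 locations")
    if np.ptp(z) == 0:
        raise DegenerateVariableError("constant values have undefined Moran's I")
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    if np.any(d[~np.eye(n, dtype=bool)] == 0):
        raise SchemaError("coordinates must be distinct")
    if weights == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif weights == "knn":
        w = np.zeros_like(d)
        order = np.argsort(d, axis=1)
        for i in range(n):
            w[i, order[i, 1 : k_neighbours + 1]] = 1.0
    else:
        raise SchemaError(f"unknown weights scheme {weights!r}")
    w /= w.sum(axis=1, keepdims=True)
    s0 = w.sum()

    zc = z - z.mean()
    denom = zc @ zc

    def moran(v: np.ndarray) -> float:
        return float(n / s0 * (v @ w @ v) / (v @ v))

    i_obs = moran(zc)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(zc)
        if abs(moran(perm) - e_i) >= abs(i_obs - e_i) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return i_obs, p
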