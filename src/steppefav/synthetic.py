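"""Synthetic landscapes, censuses and multi-year reserve counts.

The generator produces inputs with known ground truth so every downstream
stage (feature extraction, favourability modelling, extrapolation, trend and
abundance models) can be tested end to end:

* an annual series of categorical land-cover mosaics over six functional
  groups, patchy and spatially autocorrelated, split into three contiguous
  protection strata with distinct mean compositions;
* a single-year census of point counts at a minimum spacing, with presences
  drawn from a logistic habitat model on standardized buffer features whose
  intercept is calibrated to a target prevalence;
* a decade of annual counts at fixed reserve points following a Poisson
  log-linear model with a year trend, a conspecific-attraction term on
  neighbouring males, and Gaussian random point intercepts.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the config, with draws made in a fixed, documented order, so identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .config import SyntheticConfig
from .errors import InvalidConfigError, PlacementError
from .landcover import (
    EXCLUDED,
    GROUPS,
    PROTECTION_LEVELS,
    LandCoverGrid,
    LandCoverSeries,
    build_feature_table,
)
from .population import neighbouring_males

FEATURE_COLUMNS = list(GROUPS) + ["shannon"]


@dataclass
class GroundTruth:
    """Known generating parameters, the oracle for recovery tests."""

    true_beta: dict[str, float] = field(default_factory=dict)
    true_intercept: float = 0.0
    true_trend_raw: float = 0.0  # per raw year, log scale
    true_trend_std: float = 0.0  # per standardized year, log scale
    true_attraction: float = 0.0
    true_point_sd: float = 0.0
    probabilities: np.ndarray | None = None  # per-point occurrence probability
    expected_counts: np.ndarray | None = None  # per row of the census table
    neighbour_covariate: np.ndarray | None = None  # covariate used in generation
    random_intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.probabilities is not None:
            p = np.asarray(self.probabilities)
            if np.any((p < 0) | (p > 1)):
                raise ValueError("ground-truth probabilities must lie in [0, 1]")
        if self.expected_counts is not None and np.any(
            np.asarray(self.expected_counts) < 0
        ):
            raise ValueError("expected counts must be nonnegative")


# ---------------------------------------------------------------------------
# landscape


def _stratum_bands(nx: int, fractions: dict[str, float]) -> np.ndarray:
    """Column -> protection index, three contiguous vertical bands."""
    widths = np.array([fractions[k] for k in PROTECTION_LEVELS])
    edges = np.round(np.cumsum(widths) * nx).astype(int)
    col_stratum = np.empty(nx, dtype=np.int8)
    start = 0
    for idx, stop in enumerate(edges):
        col_stratum[start:stop] = idx
        start = stop
    col_stratum[start:] = len(PROTECTION_LEVELS) - 1
    return col_stratum


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Unit-variance Gaussian random field via smoothed white noise."""
    raw = rng.standard_normal(shape).astype(np.float32)
    f = gaussian_filter(raw, sigma=sigma_cells, mode="wrap")
    return f / f.std()


def _calibrate_biases(
    fields: np.ndarray, stratum_of_cell: np.ndarray, weights: np.ndarray, n_iter: int = 40
) -> np.ndarray:
    """Per-stratum softmax biases so that the expected category fraction in
    each stratum matches its target weights. Zero-weight categories are pinned
    far below the others."""
    n_strata = weights.shape[0]
    biases = np.where(weights > 0, np.log(np.maximum(weights, 1e-12)), -1e9)
    for _ in range(n_iter):
        for s in range(n_strata):
            mask = stratum_of_cell == s
            if not mask.any():
                continue
            scores = biases[s][:, None] + fields[:, mask]
            scores -= scores.max(axis=0, keepdims=True)
            p = np.exp(scores)
            p /= p.sum(axis=0, keepdims=True)
            realized = p.mean(axis=1)
            with np.errstate(divide="ignore"):
                adj = np.log(np.maximum(weights[s], 1e-300)) - np.log(
                    np.maximum(realized, 1e-300)
                )
            biases[s] = np.where(weights[s] > 0, biases[s] + adj, -1e9)
    return biases


def generate_landscape(config: SyntheticConfig) -> LandCoverSeries:
    """Annual categorical mosaics over the six functional groups.

    Each category gets a Gaussian random field of scores; per-cell category
    probabilities are the softmax of (per-stratum bias + field), with biases
    calibrated so each stratum's expected composition matches its configured
    weights. Cells are hard-assigned with the Gumbel-argmax trick using one
    fixed Gumbel draw per cell and category, so assignments are exact softmax
    samples yet change between years only where the fields drift (AR(1)
    evolution with persistence ``year_rho``).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    w, h = config.extent
    nx = int(round(w / config.fine_cell))
    ny = int(round(h / config.fine_cell))
    categories = tuple(GROUPS) + (EXCLUDED,)
    k = len(categories)
    sigma = config.corr_length / config.fine_cell

    col_stratum = _stratum_bands(nx, config.protection_fractions)
    protection = np.broadcast_to(col_stratum, (ny, nx)).copy()

    weights = np.array(
        [
            [config.stratum_weights[s].get(g, 0.0) for g in categories]
            for s in PROTECTION_LEVELS
        ]
    )

    # draw order: fields (year 1), gumbel noise, then AR(1) innovations per year
    fields = np.stack([_smooth_field(rng, (ny, nx), sigma) for _ in range(k)])
    fields *= config.field_sd
    gumbel = rng.gumbel(size=(k, ny, nx)).astype(np.float32)

    stratum_flat = protection.ravel()
    biases = _calibrate_biases(
        fields.reshape(k, -1), stratum_flat, weights
    )

    series = LandCoverSeries()
    bias_map = biases[stratum_flat].T.reshape(k, ny, nx)  # (k, ny, nx)
    rho = config.year_rho
    for i, year in enumerate(config.year_list):
        if i > 0:
            innov = np.stack([_smooth_field(rng, (ny, nx), sigma) for _ in range(k)])
            fields = rho * fields + np.sqrt(1 - rho**2) * config.field_sd * innov
        labels = np.argmax(bias_map + fields + gumbel, axis=0).astype(np.int64)
        series.grids[year] = LandCoverGrid(
            year=year,
            cell_size=config.fine_cell,
            origin=(0.0, 0.0),
            categories=categories,
            labels=labels,
            protection=protection,
        )
    return series


# ---------------------------------------------------------------------------
# point placement


def _place_points(
    rng: np.random.Generator,
    n: int,
    x_range: tuple[float, float],
    y_range: tuple[float, float],
    min_spacing: float,
    max_attempts_per_point: int = 500,
) -> np.ndarray:
    """Random sequential placement at a minimum spacing (dart throwing)."""
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = max_attempts_per_point * n
    while placed < n:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n} points at {min_spacing} m spacing "
                f"inside x={x_range}, y={y_range} ({placed} placed)"
            )
        cand = np.array(
            [rng.uniform(*x_range), rng.uniform(*y_range)]
        )
        attempts += 1
        if placed:
            d2 = ((pts[:placed] - cand) ** 2).sum(axis=1)
            if d2.min() < min_spacing**2:
                continue
        pts[placed] = cand
        placed += 1
    return pts


def _calibrate_intercept(linear_predictor: np.ndarray, target: float) -> float:
    """Intercept such that mean logistic probability equals the target."""

    def gap(b0: float) -> float:
        return expit(b0 + linear_predictor).mean() - target

    return brentq(gap, -30.0, 30.0, xtol=1e-12)


def _protection_label(x: np.ndarray, extent_x: float, fractions: dict) -> np.ndarray:
    edges = np.cumsum([fractions[k] for k in PROTECTION_LEVELS]) * extent_x
    idx = np.searchsorted(edges, x, side="right")
    idx = np.minimum(idx, len(PROTECTION_LEVELS) - 1)
    return np.array(PROTECTION_LEVELS, dtype=object)[idx]


# ---------------------------------------------------------------------------
# single-year census


def generate_census(
    landscape: LandCoverSeries, config: SyntheticConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """One breeding-season census with known occurrence model.

    Points are placed at >= ``min_spacing`` across the whole extent; presence
    is Bernoulli from a logistic model on standardized buffer features with
    slopes ``true_beta`` and an intercept calibrated by root finding so the
    expected prevalence equals ``target_prevalence``. Male counts at occupied
    points follow a two-round lek-like process: a seed count, then
    attraction-weighted reinforcement from males within 1.7 km, which makes
    counts cluster spatially.
    """
    config.validate()
    year = config.census_year
    if year not in landscape.grids:
        raise InvalidConfigError(f"landscape lacks census year {year}")
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 1)))
    w, h = config.extent
    margin = config.buffer_radius
    pts = _place_points(
        rng, config.n_points, (margin, w - margin), (margin, h - margin), config.min_spacing
    )
    points = pd.DataFrame(
        {
            "point_id": [f"P{i:04d}" for i in range(config.n_points)],
            "x": pts[:, 0],
            "y": pts[:, 1],
            "year": year,
        }
    )
    feats = build_feature_table(landscape, points, radius=config.buffer_radius)

    z = feats[FEATURE_COLUMNS].to_numpy(dtype=float)
    z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
    slopes = np.array([config.true_beta.get(c, 0.0) for c in FEATURE_COLUMNS])
    lp = z @ slopes
    b0 = _calibrate_intercept(lp, config.target_prevalence)
    prob = expit(b0 + lp)
    presence = rng.random(config.n_points) < prob

    males = np.zeros(config.n_points, dtype=int)
    males[presence] = 1 + rng.poisson(0.3, size=presence.sum())
    table = feats.copy()
    table["males"] = males
    neigh = neighbouring_males(table.assign(year=year), radius=1700.0).to_numpy()
    extra = rng.poisson(config.attraction_strength * neigh[presence])
    males[presence] += extra
    table["males"] = males
    table["presence"] = (males > 0).astype(int)
    table["protection"] = _protection_label(pts[:, 0], w, config.protection_fractions)

    truth = GroundTruth(
        true_beta={c: config.true_beta.get(c, 0.0) for c in FEATURE_COLUMNS},
        true_intercept=b0,
        true_attraction=config.attraction_strength,
        probabilities=prob,
    )
    return table, truth


# ---------------------------------------------------------------------------
# reserve time series


def generate_reserve_timeseries(
    landscape: LandCoverSeries | None, config: SyntheticConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Annual counts at fixed reserve points with trend, attraction, and
    random point intercepts.

    For each year the log expected count is ``log(reserve_mean_males) +
    trend_std * zyear + a_i`` plus the attraction term; counts are drawn in
    two passes — a first Poisson draw without attraction fixes the neighbour
    covariate, then the final Poisson draw includes
    ``attraction_strength * neighbours``. The covariate actually used in
    generation is stored in the ground truth, since refitting needs it.

    The generating model has no habitat term, so ``landscape`` may be None;
    when given it is only validated to cover the census years.
    """
    config.validate()
    years = config.year_list
    if len(years) < 2:
        raise InvalidConfigError("reserve time series needs at least two years")
    if landscape is not None:
        missing = [y for y in years if y not in landscape.grids]
        if missing:
            raise InvalidConfigError(f"landscape lacks census years {missing}")
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 2)))
    w, h = config.extent
    reserve_width = config.protection_fractions["reserve"] * w
    margin = config.buffer_radius
    if reserve_width <= 2 * margin:
        raise PlacementError("reserve stratum too narrow for buffered points")
    pts = _place_points(
        rng,
        config.n_reserve_points,
        (margin, reserve_width - margin),
        (margin, h - margin),
        config.min_spacing,
    )
    ids = [f"R{i:03d}" for i in range(config.n_reserve_points)]

    yr = np.asarray(years, dtype=float)
    zyear = (yr - yr.mean()) / yr.std(ddof=1)
    trend_std = config.trend_log_rate * yr.std(ddof=1)
    a = rng.normal(0.0, config.point_sd, size=config.n_reserve_points)
    base = np.log(config.reserve_mean_males)

    rows = []
    mu_all, neigh_all = [], []
    for t, year in enumerate(years):
        eta0 = base + trend_std * zyear[t] + a
        counts0 = rng.poisson(np.exp(eta0))
        tmp = pd.DataFrame(
            {"point_id": ids, "x": pts[:, 0], "y": pts[:, 1], "year": year, "males": counts0}
        )
        neigh = neighbouring_males(tmp, radius=1700.0).to_numpy()
        mu = np.exp(eta0 + config.attraction_strength * neigh)
        counts = rng.poisson(mu)
        mu_all.append(mu)
        neigh_all.append(neigh)
        for i in range(config.n_reserve_points):
            rows.append(
                {
                    "point_id": ids[i],
                    "x": pts[i, 0],
                    "y": pts[i, 1],
                    "year": year,
                    "males": int(counts[i]),
                    "protection": "reserve",
                }
            )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        true_trend_raw=config.trend_log_rate,
        true_trend_std=trend_std,
        true_attraction=config.attraction_strength,
        true_point_sd=config.point_sd,
        expected_counts=np.concatenate(mu_all),
        neighbour_covariate=np.concatenate(neigh_all),
        random_intercepts=a,
    )
    return table, truth


# ---------------------------------------------------------------------------
# feature-level occurrence simulator (fast path for model-selection studies)


def simulate_occurrence_dataset(
    rng: np.random.Generator,
    n: int = 438,
    slopes: dict[str, float] | None = None,
    prevalence: float = 30 / 438,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Standardized-feature occurrence dataset with known coefficients.

    Draws independent standard-normal candidate features, calibrates the
    logistic intercept to the requested prevalence, and samples Bernoulli
    presences. Much cheaper than growing a full landscape; used for
    model-selection and recovery studies where only the regression structure
    matters.

    Returns (features, response, calibrated intercept).
    """
    if columns is None:
        columns = FEATURE_COLUMNS
    if slopes is None:
        slopes = {"seminatural": 1.0, "cereal": 1.3, "legume": 0.7}
    X = rng.standard_normal((n, len(columns)))
    beta = np.array([slopes.get(c, 0.0) for c in columns])
    lp = X @ beta
    b0 = _calibrate_intercept(lp, prevalence)
    y = (rng.random(n) < expit(b0 + lp)).astype(int)
    return pd.DataFrame(X, columns=columns), y, b0
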