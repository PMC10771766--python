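"""End-to-end analysis pipeline on synthetic or user-supplied data.

Stage order mirrors the analysis chain: buffer features -> VIF screen ->
stepwise logistic fit -> favourability model + diagnostics -> annual
extrapolation -> suitability threshold -> favourability trend GLM ->
abundance GLM -> conspecific-attraction GLMM. Any stage failure aborts with
the stage name and context. Every run is fully determined by (config, seed)
and outputs carry the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .config import PipelineConfig, SyntheticConfig, _plain
from .errors import SteppefavError
from .extrapolation import apply_threshold, predict_surfaces
from .favourability import (
    FavourabilityModel,
    auc,
    build_favourability_model,
    morans_test,
    quantile_residuals,
    standardize,
    stepwise_aic,
    vif,
)
from .landcover import GROUPS
from .population import (
    abundance_glm,
    favourability_trend_glm,
    fit_poisson_glmm,
    neighbouring_males,
)
from .synthetic import (
    FEATURE_COLUMNS,
    generate_census,
    generate_landscape,
    generate_reserve_timeseries,
)

log = logging.getLogger("steppefav")


@dataclass
class PipelineReport:
    """Everything the pipeline computed, in memory."""

    config_hash: str
    vif_table: pd.DataFrame | None = None
    model: FavourabilityModel | None = None
    surfaces: pd.DataFrame | None = None
    panel: pd.DataFrame | None = None
    threshold_report: dict = field(default_factory=dict)
    trend_estimates: pd.Series | None = None
    trend_anova: pd.DataFrame | None = None
    trend_moran: tuple[float, float] | None = None
    abundance: object = None
    glmm: object = None
    census: pd.DataFrame | None = None
    reserve: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def config_hash(config: PipelineConfig) -> str:
    from dataclasses import asdict

    text = yaml.safe_dump(_plain(asdict(config)), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except SteppefavError as exc:
            raise SteppefavError(f"pipeline stage '{name}' failed: {exc}") from exc

    return wrap


def cell_favourability_at_points(
    surfaces: pd.DataFrame, points: pd.DataFrame, coarse_cell: float
) -> np.ndarray:
    """Favourability of the coarse cell containing each point, per year."""
    lookup = surfaces.set_index(["cell_x", "cell_y", "year"])["favourability"]
    cx = (np.floor(points["x"] / coarse_cell) + 0.5) * coarse_cell
    cy = (np.floor(points["y"] / coarse_cell) + 0.5) * coarse_cell
    keys = list(zip(cx, cy, points["year"]))
    return lookup.loc[keys].to_numpy()


def run_pipeline(config: PipelineConfig, out_dir=None) -> PipelineReport:
    """Run every analysis stage on a synthetic study and return the report.

    When ``out_dir`` is given, artifacts are written there: census and
    reserve CSVs, the model JSON, the surface CSV, result tables, and a run
    log carrying the seed and the config hash.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    syn = config.synthetic or SyntheticConfig(rng_seed=config.rng_seed)
    chash = config_hash(config)
    report = PipelineReport(config_hash=chash)

    landscape = _stage("simulate-landscape")(generate_landscape, syn)
    census, census_truth = _stage("simulate-census")(generate_census, landscape, syn)
    reserve, reserve_truth = _stage("simulate-reserve")(
        generate_reserve_timeseries, landscape, syn
    )
    report.census, report.reserve = census, reserve
    n_presence = int(census["presence"].sum())
    log.info("census: %d points, %d presences", len(census), n_presence)

    # --- features -> VIF -> stepwise fit -> favourability
    features = census[FEATURE_COLUMNS]
    std_features, standardizer = _stage("standardize")(standardize, features)
    report.vif_table = _stage("vif")(vif, std_features, config.vif_limit)
    fit = _stage("stepwise-fit")(stepwise_aic, census["presence"], std_features)
    model = _stage("favourability")(build_favourability_model, fit, standardizer)
    model.auc = auc(fit.fitted, census["presence"])
    resid = quantile_residuals(fit.fitted, census["presence"], rng_seed=config.rng_seed)
    model.moran_i, model.moran_p = _stage("moran-occurrence")(
        morans_test, resid, census[["x", "y"]].to_numpy(), 999, config.rng_seed
    )
    report.model = model
    log.info(
        "selected %s | AUC %.3f | Moran p %.3f", fit.variables, model.auc, model.moran_p
    )

    # --- extrapolation, threshold, trend model
    surfaces = _stage("extrapolate")(predict_surfaces, model, landscape, config.coarse_cell)
    report.surfaces = surfaces
    panel, threshold_report = _stage("threshold")(
        apply_threshold, surfaces, config.favourability_threshold
    )
    report.panel, report.threshold_report = panel, threshold_report
    log.info(
        "threshold %.2f retained %d / %d cell-years",
        config.favourability_threshold,
        threshold_report["n_retained"],
        threshold_report["n_input"],
    )
    estimates, anova = _stage("trend-glm")(favourability_trend_glm, panel)
    report.trend_estimates, report.trend_anova = estimates, anova

    # Moran on cell-mean gaussian quantile residuals of the trend model
    resid_panel = panel.copy()
    resid_panel["resid"] = _trend_residuals(panel, estimates)
    cell_means = (
        resid_panel.groupby(["cell_x", "cell_y"])["resid"].mean().reset_index()
    )
    sd = resid_panel["resid"].std(ddof=1)
    z_resid = (cell_means["resid"] / sd).to_numpy()
    report.trend_moran = _stage("moran-trend")(
        morans_test, z_resid, cell_means[["cell_x", "cell_y"]].to_numpy(), 999,
        config.rng_seed,
    )

    # --- abundance and GLMM
    report.abundance = _stage("abundance-glm")(
        abundance_glm, census["males"], census["protection"]
    )
    neigh = _stage("neighbours")(neighbouring_males, reserve, config.neighbour_radius)
    fav_at_points = _stage("favourability-at-points")(
        cell_favourability_at_points, surfaces, reserve, config.coarse_cell
    )
    years = reserve["year"].astype(float)
    zyear = (years - years.mean()) / years.std(ddof=1)
    covariates = pd.DataFrame(
        {
            "year": zyear.to_numpy(),
            "favourability": fav_at_points,
            "neighbouring_males": neigh.to_numpy(),
        }
    )
    report.glmm = _stage("glmm")(
        fit_poisson_glmm, reserve["males"], covariates, reserve["point_id"]
    )

    report.summary = {
        "config_hash": chash,
        "seed": config.rng_seed,
        "n_points": int(len(census)),
        "n_presences": n_presence,
        "prevalence": n_presence / len(census),
        "selected_variables": fit.variables,
        "auc": model.auc,
        "moran_p_occurrence": model.moran_p,
        "n_cells_retained": threshold_report["n_retained"],
        "trend_moran_p": report.trend_moran[1],
        "abundance_lr_chi2": report.abundance.lr_chi2,
        "abundance_lr_p": report.abundance.lr_p,
        "glmm_sigma": report.glmm.sigma,
        "glmm_dispersion": report.glmm.dispersion,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_census(census, out / "census.csv")
        sio.write_census(reserve, out / "reserve_census.csv")
        model.to_json(out / "model.json")
        sio.write_surfaces(surfaces, out / "surfaces.csv")
        report.trend_anova.to_csv(out / "trend_anova.csv")
        report.glmm.term_tests.to_csv(out / "glmm_terms.csv")
        sio.write_ground_truth(census_truth, out / "ground_truth_census.json")
        sio.write_ground_truth(reserve_truth, out / "ground_truth_reserve.json")
        with open(out / "run_log.json", "w") as fh:
            json.dump(report.summary, fh, indent=2, default=float)
    return report


def _trend_residuals(panel: pd.DataFrame, estimates: pd.Series) -> np.ndarray:
    """Residuals of the trend OLS recomputed from its estimates."""
    from .population import _sum_contrasts

    levels = sorted(panel["protection"].unique())
    years = panel["year"].astype(float)
    zyear = ((years - years.mean()) / years.std(ddof=1)).to_numpy()
    prot = _sum_contrasts(levels, panel["protection"])
    X = np.column_stack(
        [np.ones(len(panel)), zyear[:, None], prot, prot * zyear[:, None]]
    )
    return panel["favourability"].to_numpy() - X @ estimates.to_numpy()
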