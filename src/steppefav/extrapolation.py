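"""Project a fitted favourability model onto coarse composition grids.

The model is trained on buffer proportions in [0, 1]; coarse-grid fractions
are already on that scale, which is asserted at prediction time. Each
cell-year gets a favourability value from the shifted-intercept (prevalence
corrected) form of the model, producing the panel used by the trend analysis.
Cells whose favourability stays below a threshold (0.2 by default, the usual
cut-off for habitat judged unsuitable for the species) are discarded before
trend modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import SchemaError
from .favourability import FavourabilityModel
from .landcover import GROUPS, PROTECTION_LEVELS, LandCoverGrid, LandCoverSeries


def surface_frame(grid: LandCoverGrid) -> pd.DataFrame:
    """Flatten a coarse fractional grid into one row per cell."""
    if grid.fractions is None:
        raise SchemaError("predict_surface expects a coarse fractional grid")
    ny, nx = grid.shape
    xs, ys = grid.cell_centres()
    gx, gy = np.meshgrid(xs, ys)
    data = {"cell_x": gx.ravel(), "cell_y": gy.ravel()}
    for i, cat in enumerate(grid.categories):
        data[cat] = grid.fractions[:, :, i].ravel()
    if grid.protection is not None:
        data["protection"] = np.array(PROTECTION_LEVELS, dtype=object)[
            grid.protection.ravel()
        ]
    out = pd.DataFrame(data)
    group_cols = [g for g in GROUPS if g in out.columns]
    comp = out[group_cols].to_numpy(dtype=float)
    total = comp.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, comp / total, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    out["shannon"] = -plogp.sum(axis=1)
    out["year"] = grid.year
    return out


def predict_surface(model: FavourabilityModel, coarse: LandCoverGrid) -> pd.DataFrame:
    """Favourability per coarse cell for one year.

    Cell fractions are standardized with the *training* standardizer (so the
    fitted coefficients keep their meaning) and pushed through the
    favourability form of the model. Returns columns
    ``cell_x, cell_y, year, favourability[, protection]``.
    """
    frame = surface_frame(coarse)
    needed = set(model.fit.variables)
    missing = needed - set(frame.columns)
    if missing:
        raise SchemaError(f"coarse grid lacks model variables: {sorted(missing)}")
    for v in model.standardizer.means.index:
        if v in frame.columns and v in GROUPS:  # proportion-scale check only
            vals = frame[v].to_numpy(dtype=float)
            if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
                raise SchemaError(
                    f"variable {v!r} not on the training proportion scale [0, 1]"
                )
    fav = model.predict_favourability(frame)
    cols = ["cell_x", "cell_y", "year"]
    if "protection" in frame.columns:
        cols.append("protection")
    out = frame[cols].copy()
    out["favourability"] = fav
    return out


def predict_surfaces(
    model: FavourabilityModel, series: LandCoverSeries, coarse_cell: float = 1000.0
) -> pd.DataFrame:
    """Annual favourability surfaces for every year of a land-cover series."""
    from .landcover import cell_composition

    frames = []
    for year in series.years:
        grid = series[year]
        coarse = grid if grid.fractions is not None else cell_composition(grid, coarse_cell)
        frames.append(predict_surface(model, coarse))
    return pd.concat(frames, ignore_index=True)


def apply_threshold(
    surfaces: pd.DataFrame, threshold: float = 0.2, per_year: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Discard low-favourability cells before trend analysis.

    By default a cell is retained when its across-year *mean* favourability
    reaches the threshold, which keeps the panel balanced (every retained cell
    contributes every year); ``per_year=True`` filters cell-years
    individually instead. Returns the retained panel and a report with
    retained/discarded counts.
    """
    required = {"cell_x", "cell_y", "year", "favourability"}
    missing = required - set(surfaces.columns)
    if missing:
        raise SchemaError(f"surface panel missing columns: {sorted(missing)}")
    if per_year:
        keep = surfaces["favourability"] >= threshold
        panel = surfaces[keep].reset_index(drop=True)
    else:
        means = surfaces.groupby(["cell_x", "cell_y"])["favourability"].transform("mean")
        panel = surfaces[means >= threshold].reset_index(drop=True)
    report = {
        "threshold": threshold,
        "per_year": per_year,
        "n_input": int(len(surfaces)),
        "n_retained": int(len(panel)),
        "n_discarded": int(len(surfaces) - len(panel)),
    }
    if len(panel) == 0:
        warnings.warn(
            f"favourability threshold {threshold} left an empty panel", stacklevel=2
        )
    return panel, report
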