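"""CSV/JSON readers and writers with validation.

All tables are comma-separated UTF-8 with mandatory headers and "." decimals.
Readers validate every invariant they can and report *all* violations in one
error message rather than failing on the first.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import SchemaError
from .landcover import (
    GROUPS,
    PROTECTION_LEVELS,
    LandCoverGrid,
    LandCoverSeries,
)

CENSUS_COLUMNS = ["point_id", "x", "y", "year", "males"]


def read_census(path) -> pd.DataFrame:
    """Read and validate a census table.

    Required columns: point_id, x, y, year, males. Optional: females,
    protection, presence. Counts must be nonnegative integers, coordinates
    finite, and (point_id, year) unique.
    """
    table = pd.read_csv(path)
    problems: list[str] = []
    missing = [c for c in CENSUS_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"census file missing columns: {missing}")
    for col in ["males"] + (["females"] if "females" in table.columns else []):
        vals = table[col]
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        for idx in table.index[bad]:
            problems.append(f"row {idx}: {col} = {vals[idx]!r} is not a nonnegative integer")
    for col in ("x", "y"):
        bad = ~np.isfinite(table[col].to_numpy(dtype=float))
        for idx in table.index[bad]:
            problems.append(f"row {idx}: non-finite coordinate {col}")
    dups = table.duplicated(["point_id", "year"])
    for idx in table.index[dups]:
        problems.append(
            f"row {idx}: duplicate (point_id, year) = "
            f"({table.at[idx, 'point_id']!r}, {table.at[idx, 'year']!r})"
        )
    if "protection" in table.columns:
        bad = ~table["protection"].isin(PROTECTION_LEVELS)
        for idx in table.index[bad]:
            problems.append(f"row {idx}: unknown protection {table.at[idx, 'protection']!r}")
    if problems:
        raise SchemaError("invalid census file:\n  " + "\n  ".join(problems))
    table["males"] = table["males"].astype(int)
    return table


def write_census(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_landcover_series(series: LandCoverSeries, path) -> None:
    """Write a fine categorical series as long CSV:
    cell_x, cell_y, cell_size, year, category[, protection]."""
    frames = []
    for year in series.years:
        grid = series[year]
        if grid.labels is None:
            raise SchemaError("long land-cover CSV writer expects categorical grids")
        xs, ys = grid.cell_centres()
        gx, gy = np.meshgrid(xs, ys)
        frame = pd.DataFrame(
            {
                "cell_x": gx.ravel(),
                "cell_y": gy.ravel(),
                "cell_size": grid.cell_size,
                "year": year,
                "category": np.array(grid.categories, dtype=object)[grid.labels.ravel()],
            }
        )
        if grid.protection is not None:
            frame["protection"] = np.array(PROTECTION_LEVELS, dtype=object)[
                grid.protection.ravel()
            ]
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_landcover_series(path) -> LandCoverSeries:
    """Read a fine categorical series from the long CSV format."""
    table = pd.read_csv(path)
    required = {"cell_x", "cell_y", "cell_size", "year", "category"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"land-cover file missing columns: {sorted(missing)}")
    series = LandCoverSeries()
    categories = tuple(
        [g for g in GROUPS if g in set(table["category"])]
        + sorted(set(table["category"]) - set(GROUPS))
    )
    cat_idx = {c: i for i, c in enumerate(categories)}
    prot_idx = {p: i for i, p in enumerate(PROTECTION_LEVELS)}
    for year, grp in table.groupby("year"):
        s = float(grp["cell_size"].iloc[0])
        xs = np.sort(grp["cell_x"].unique())
        ys = np.sort(grp["cell_y"].unique())
        origin = (float(xs[0] - s / 2), float(ys[0] - s / 2))
        nx, ny = len(xs), len(ys)
        if len(grp) != nx * ny:
            raise SchemaError(f"year {year}: grid is not a complete rectangle")
        jj = np.rint((grp["cell_x"].to_numpy() - origin[0] - s / 2) / s).astype(int)
        ii = np.rint((grp["cell_y"].to_numpy() - origin[1] - s / 2) / s).astype(int)
        labels = np.zeros((ny, nx), dtype=np.int64)
        labels[ii, jj] = grp["category"].map(cat_idx).to_numpy()
        protection = None
        if "protection" in grp.columns:
            protection = np.zeros((ny, nx), dtype=np.int8)
            protection[ii, jj] = grp["protection"].map(prot_idx).to_numpy()
        series.grids[int(year)] = LandCoverGrid(
            year=int(year), cell_size=s, origin=origin,
            categories=categories, labels=labels, protection=protection,
        )
    return series


def write_surfaces(surfaces: pd.DataFrame, path) -> None:
    """Per-year favourability surface CSV:
    cell_x, cell_y, year, favourability[, protection]."""
    cols = ["cell_x", "cell_y", "year", "favourability"]
    if "protection" in surfaces.columns:
        cols.append("protection")
    surfaces[cols].to_csv(path, index=False)


def read_surfaces(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"cell_x", "cell_y", "year", "favourability"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"surface file missing columns: {sorted(missing)}")
    bad = (table["favourability"] < 0) | (table["favourability"] > 1)
    if bad.any():
        raise SchemaError("favourability values outside [0, 1]")
    return table


def write_ground_truth(truth, path) -> None:
    payload = {}
    for key, value in vars(truth).items():
        if isinstance(value, np.ndarray):
            payload[key] = value.tolist()
        else:
            payload[key] = value
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
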