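"""Land-cover grids, reclassification, and buffer/cell composition features.

Grids live in a projected metric CRS. A grid's origin is its lower-left corner
and cells are half-open squares ``[x, x + s) x [y, y + s)``. Fine grids carry a
categorical label per cell; coarse grids carry a fraction vector over the
functional land-use groups. Functional groups are the six classes relevant to
steppe-bird habitat selection::

    cereal, legume, seminatural, woody, urban, other

Raw land-cover products typically distinguish many more classes (irrigated vs
rain-fed crops, several natural-vegetation types, rare classes like water);
:class:`ReclassMap` collapses them onto the functional groups, optionally
routing rare classes to an explicit ``excluded`` label that reduces buffer
proportion sums below one instead of being renormalized away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BoundaryError,
    InvalidConfigError,
    ReclassificationError,
    SchemaError,
    UndefinedDiversityError,
)

#: Default functional land-use groups, in canonical order.
GROUPS = ("cereal", "legume", "seminatural", "woody", "urban", "other")

#: Label for cells excluded from analysis (rare classes such as water).
EXCLUDED = "excluded"

#: Protection strata, from most to least protected.
PROTECTION_LEVELS = ("reserve", "spa", "unprotected")


@dataclass
class LandCoverGrid:
    """One year of land cover, either categorical (fine) or fractional (coarse).

    Parameters
    ----------
    year : int
        Calendar year the grid describes.
    cell_size : float
        Cell edge length in metres.
    origin : tuple of float
        ``(x0, y0)`` of the lower-left grid corner, metres.
    categories : tuple of str
        Group labels. Index ``i`` in ``labels`` / axis 2 of ``fractions``
        refers to ``categories[i]``. May include :data:`EXCLUDED`.
    labels : ndarray of int, shape (ny, nx), optional
        Per-cell category index (fine grids).
    fractions : ndarray of float, shape (ny, nx, k), optional
        Per-cell fraction of each category (coarse grids). Rows sum to 1
        over all categories including ``excluded``.
    protection : ndarray of int, shape (ny, nx), optional
        Per-cell index into :data:`PROTECTION_LEVELS`.
    """

    year: int
    cell_size: float
    origin: tuple[float, float]
    categories: tuple[str, ...]
    labels: np.ndarray | None = None
    fractions: np.ndarray | None = None
    protection: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if (self.labels is None) == (self.fractions is None):
            raise SchemaError("grid must carry exactly one of labels / fractions")
        if self.fractions is not None:
            sums = self.fractions.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise SchemaError("fraction vectors must sum to 1 +/- 1e-9")

    @property
    def shape(self) -> tuple[int, int]:
        arr = self.labels if self.labels is not None else self.fractions
        return arr.shape[0], arr.shape[1]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) in metres."""
        ny, nx = self.shape
        return nx * self.cell_size, ny * self.cell_size

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays of x and y centre coordinates (1-d, along each axis)."""
        ny, nx = self.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def group_fractions(self) -> pd.Series:
        """Whole-grid fraction of each category (area-weighted)."""
        if self.labels is not None:
            counts = np.bincount(self.labels.ravel(), minlength=len(self.categories))
            return pd.Series(counts / counts.sum(), index=list(self.categories))
        return pd.Series(
            self.fractions.mean(axis=(0, 1)), index=list(self.categories)
        )


@dataclass
class LandCoverSeries:
    """Annual sequence of grids sharing geometry, categories and protection."""

    grids: dict[int, LandCoverGrid] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.grids)

    def __getitem__(self, year: int) -> LandCoverGrid:
        if year not in self.grids:
            raise KeyError(f"no land-cover grid for year {year}")
        return self.grids[year]

    def __len__(self) -> int:
        return len(self.grids)


@dataclass
class ReclassMap:
    """Mapping from raw land-cover codes onto the functional groups.

    ``mapping`` sends each raw code (any hashable, usually str or int) to one
    of ``groups`` or to :data:`EXCLUDED`.
    """

    mapping: dict
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        allowed = set(self.groups) | {EXCLUDED}
        bad = {v for v in self.mapping.values() if v not in allowed}
        if bad:
            raise InvalidConfigError(f"reclass targets not in group set: {sorted(bad)}")

    @classmethod
    def identity(cls, groups: tuple[str, ...] = GROUPS) -> "ReclassMap":
        """Map already-grouped labels onto themselves."""
        return cls({g: g for g in groups}, groups=groups)


def reclassify(
    raw_grid: LandCoverGrid, reclass_map: ReclassMap, strict: bool = True
) -> LandCoverGrid:
    """Collapse a raw categorical grid onto the functional groups.

    Unknown raw codes raise :class:`ReclassificationError` naming the code
    when ``strict``; otherwise they are routed to ``excluded``. Excluded
    cells keep an explicit label — they are flagged, never dropped.
    """
    if raw_grid.labels is None:
        raise SchemaError("reclassify expects a categorical (fine) grid")
    out_categories = tuple(reclass_map.groups) + (EXCLUDED,)
    index_of = {c: i for i, c in enumerate(out_categories)}
    lut = np.empty(len(raw_grid.categories), dtype=np.int64)
    for i, code in enumerate(raw_grid.categories):
        target = reclass_map.mapping.get(code)
        if target is None:
            if strict:
                raise ReclassificationError(
                    f"raw land-cover code {code!r} missing from reclassification map"
                )
            target = EXCLUDED
        lut[i] = index_of[target]
    return LandCoverGrid(
        year=raw_grid.year,
        cell_size=raw_grid.cell_size,
        origin=raw_grid.origin,
        categories=out_categories,
        labels=lut[raw_grid.labels],
        protection=raw_grid.protection,
    )


def _buffer_offsets(radius: float, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets (relative to the cell containing the point) whose cell
    centres can possibly fall inside the buffer; exact membership is decided
    per point."""
    r_cells = int(np.ceil(radius / cell_size)) + 1
    dj, di = np.meshgrid(np.arange(-r_cells, r_cells + 1), np.arange(-r_cells, r_cells + 1))
    return di.ravel(), dj.ravel()


def buffer_composition(
    grid: LandCoverGrid, point: tuple[float, float], radius: float = 250.0
) -> pd.Series:
    """Fraction of buffer area per category around ``point``.

    Membership is by cell-centre containment: a cell belongs to the buffer if
    its centre lies within ``radius`` of the point; the denominator is the
    number of member cells. At 10–20 m cells against a 250 m radius the area
    error of this rule is below one percent.

    Raises
    ------
    BoundaryError
        If the buffer disc extends beyond the grid extent (no silent
        truncation of partially covered buffers).
    """
    if grid.labels is None:
        raise SchemaError("buffer_composition expects a categorical (fine) grid")
    x, y = point
    x0, y0 = grid.origin
    w, h = grid.extent
    if not (x0 + radius <= x <= x0 + w - radius and y0 + radius <= y <= y0 + h - radius):
        raise BoundaryError(
            f"buffer of radius {radius} m around ({x:.1f}, {y:.1f}) extends beyond grid"
        )
    s = grid.cell_size
    ci = int((y - y0) // s)
    cj = int((x - x0) // s)
    di, dj = _buffer_offsets(radius, s)
    ii, jj = ci + di, cj + dj
    ny, nx = grid.shape
    inside = (ii >= 0) & (ii < ny) & (jj >= 0) & (jj < nx)
    ii, jj = ii[inside], jj[inside]
    cx = x0 + (jj + 0.5) * s
    cy = y0 + (ii + 0.5) * s
    member = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
    labels = grid.labels[ii[member], jj[member]]
    counts = np.bincount(labels, minlength=len(grid.categories))
    return pd.Series(counts / counts.sum(), index=list(grid.categories))


def shannon_index(proportions) -> float:
    """Shannon diversity H = -sum p ln p (natural log) of a composition.

    Zero entries contribute nothing (0 ln 0 := 0). The vector is renormalized
    over its nonzero mass, so compositions that sum below one (because of
    excluded classes) are handled consistently.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise UndefinedDiversityError("proportions must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise UndefinedDiversityError("all-zero composition has undefined diversity")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def cell_composition(fine_grid: LandCoverGrid, coarse_cell: float = 1000.0) -> LandCoverGrid:
    """Aggregate a fine categorical grid to coarse fractional cells.

    Each coarse cell's fraction vector is the share of its member fine cells
    per category; the protection label is the majority label of member cells.
    Mass is conserved exactly: area-weighted coarse totals equal fine totals.
    """
    if fine_grid.labels is None:
        raise SchemaError("cell_composition expects a categorical (fine) grid")
    s = fine_grid.cell_size
    ratio = coarse_cell / s
    if abs(ratio - round(ratio)) > 1e-9:
        raise InvalidConfigError(
            f"coarse cell ({coarse_cell} m) must be an integer multiple of fine cell ({s} m)"
        )
    ratio = int(round(ratio))
    ny, nx = fine_grid.shape
    if ny % ratio or nx % ratio:
        raise InvalidConfigError("grid extent is not divisible by the coarse cell size")
    cy, cx = ny // ratio, nx // ratio
    k = len(fine_grid.categories)
    blocks = fine_grid.labels.reshape(cy, ratio, cx, ratio)
    onehot = blocks[..., None] == np.arange(k)
    fractions = onehot.mean(axis=(1, 3)).astype(float)

    protection = None
    if fine_grid.protection is not None:
        pblocks = fine_grid.protection.reshape(cy, ratio, cx, ratio)
        nlev = int(fine_grid.protection.max()) + 1
        pcounts = (pblocks[..., None] == np.arange(nlev)).sum(axis=(1, 3))
        protection = pcounts.argmax(axis=2)

    return LandCoverGrid(
        year=fine_grid.year,
        cell_size=coarse_cell,
        origin=fine_grid.origin,
        categories=fine_grid.categories,
        fractions=fractions,
        protection=protection,
    )


def build_feature_table(
    series: LandCoverSeries,
    points: pd.DataFrame,
    radius: float = 250.0,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Per point-year buffer compositions plus the Shannon index.

    ``points`` needs columns ``point_id, x, y, year``; any further columns
    (presence, males, protection) are carried through. The Shannon index is
    computed over the analysed groups only (excluded mass does not enter).
    """
    required = {"point_id", "x", "y", "year"}
    missing = required - set(points.columns)
    if missing:
        raise SchemaError(f"points table missing columns: {sorted(missing)}")
    rows = []
    for _, rec in points.iterrows():
        grid = series[int(rec["year"])]
        comp = buffer_composition(grid, (rec["x"], rec["y"]), radius=radius)
        feats = {g: comp.get(g, 0.0) for g in groups}
        feats["shannon"] = shannon_index([feats[g] for g in groups])
        rows.append({**rec.to_dict(), **feats})
    return pd.DataFrame(rows)
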