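"""Configuration objects for the synthetic generator and the pipeline.

Both configs round-trip through YAML so that runs are fully described by a
single file plus a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .errors import InvalidConfigError
from .landcover import GROUPS, PROTECTION_LEVELS

# Mean composition per protection stratum. Legume and woody shares follow the
# study system (legumes ~19/13/9 %, tree cover ~2/9/17 % from reserve to
# unprotected); cereal dominates everywhere, seminatural cover mirrors the
# conservation gradient. A small "excluded" class stands in for rare cover
# types (water, horticulture) that are left out of analysis, so analysed
# proportions sum below 1 as in real land-cover products.
DEFAULT_STRATUM_WEIGHTS: dict[str, dict[str, float]] = {
    "reserve": {"cereal": 0.53, "legume": 0.185, "seminatural": 0.175,
                "woody": 0.02, "urban": 0.03, "other": 0.03, "excluded": 0.03},
    "spa": {"cereal": 0.56, "legume": 0.125, "seminatural": 0.125,
            "woody": 0.09, "urban": 0.04, "other": 0.03, "excluded": 0.03},
    "unprotected": {"cereal": 0.58, "legume": 0.085, "seminatural": 0.085,
                    "woody": 0.17, "urban": 0.03, "other": 0.02, "excluded": 0.03},
}

# Occurrence model used to simulate presences: slopes on standardized buffer
# proportions. Matches the habitat-selection structure of the study species:
# occurrence rises with seminatural, cereal and legume cover.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "seminatural": 1.0,
    "cereal": 1.3,
    "legume": 0.7,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape / census generator.

    The defaults emulate the study conditions: 438 census points with ~30
    presences (prevalence about 6.8 %), 72 reserve points censused every year
    2011-2020 with a ~50 % decline in males over the decade, lek-like spatial
    clustering of males, and annual land-cover mosaics across three protection
    strata.
    """

    rng_seed: int = 0
    extent: tuple[float, float] = (24000.0, 24000.0)  # metres
    fine_cell: float = 20.0
    coarse_cell: float = 1000.0
    n_points: int = 438
    n_reserve_points: int = 72
    years: tuple[int, int] = (2011, 2020)
    census_year: int = 2016
    true_beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    target_prevalence: float = 30 / 438
    protection_fractions: dict[str, float] = field(
        default_factory=lambda: {"reserve": 0.12, "spa": 0.25, "unprotected": 0.63}
    )
    stratum_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_STRATUM_WEIGHTS.items()}
    )
    # per-raw-year change in log expected males: 50 % decline over 9 year steps
    trend_log_rate: float = math.log(0.5) / 9.0
    attraction_strength: float = 0.1
    point_sd: float = math.sqrt(0.3)
    reserve_mean_males: float = 0.35  # expected males/point in the middle year
    min_spacing: float = 600.0
    buffer_radius: float = 250.0
    field_sd: float = 1.5  # softmax score spread -> patch contrast
    corr_length: float = 300.0  # metres, Gaussian field correlation length
    year_rho: float = 0.9  # AR(1) persistence of fields between years

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        w, h = self.extent
        for dim in (w, h):
            if abs(dim / self.fine_cell - round(dim / self.fine_cell)) > 1e-9:
                raise InvalidConfigError("extent must be divisible by fine_cell")
        ratio = self.coarse_cell / self.fine_cell
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidConfigError("fine_cell must divide coarse_cell")
        if self.n_points <= 0:
            raise InvalidConfigError("n_points must be positive")
        if not 0 < self.target_prevalence < 1:
            raise InvalidConfigError("target_prevalence must lie in (0, 1)")
        total = sum(self.protection_fractions.get(k, 0.0) for k in PROTECTION_LEVELS)
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError("protection_fractions must sum to 1")
        if self.years[1] < self.years[0]:
            raise InvalidConfigError("years range must be increasing")
        if not self.years[0] <= self.census_year <= self.years[1]:
            raise InvalidConfigError("census_year must fall inside the years range")
        for stratum, weights in self.stratum_weights.items():
            if stratum not in PROTECTION_LEVELS:
                raise InvalidConfigError(f"unknown protection stratum {stratum!r}")
            wsum = sum(weights.values())
            if abs(wsum - 1.0) > 1e-6:
                raise InvalidConfigError(
                    f"stratum {stratum!r} category weights sum to {wsum}, not 1"
                )
            unknown = set(weights) - set(GROUPS) - {"excluded"}
            if unknown:
                raise InvalidConfigError(f"unknown categories {sorted(unknown)}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("extent", "years"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters with the study defaults."""

    rng_seed: int = 0
    buffer_radius: float = 250.0
    neighbour_radius: float = 1700.0
    coarse_cell: float = 1000.0
    favourability_threshold: float = 0.2
    vif_limit: float = 5.0
    log_level: str = "INFO"
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if self.buffer_radius <= 0 or self.neighbour_radius <= 0 or self.coarse_cell <= 0:
            raise InvalidConfigError("radii and cell sizes must be positive")
        if not 0 <= self.favourability_threshold <= 1:
            raise InvalidConfigError("favourability_threshold must lie in [0, 1]")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(data), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            for key in ("extent", "years"):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            syn = SyntheticConfig(**syn)
        return cls(synthetic=syn, **raw)


def _plain(obj):
    """Recursively convert tuples / numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
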