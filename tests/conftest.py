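import numpy as np
import pytest

import steppefav as sf


@pytest.fixture(scope="session")
def small_config() -> sf.SyntheticConfig:
    """Scaled-down study: same structure, small extent for fast tests."""
    return sf.SyntheticConfig(
        rng_seed=11,
        extent=(8000.0, 8000.0),
        n_points=60,
        n_reserve_points=20,
        protection_fractions={"reserve": 0.25, "spa": 0.25, "unprotected": 0.5},
        target_prevalence=0.15,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config) -> sf.LandCoverSeries:
    return sf.generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_census(small_landscape, small_config):
    return sf.generate_census(small_landscape, small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def uniform_grid(category: int = 0, n: int = 30, cell: float = 20.0,
                 categories=sf.GROUPS, year: int = 2016) -> sf.LandCoverGrid:
    """A homogeneous categorical grid, handy for buffer tests."""
    labels = np.full((n, n), category, dtype=np.int64)
    return sf.LandCoverGrid(
        year=year, cell_size=cell, origin=(0.0, 0.0),
        categories=tuple(categories), labels=labels,
    )
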