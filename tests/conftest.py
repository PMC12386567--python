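import numpy as np
import pytest

from pestclim.climex_engine import load_default_params
from pestclim.synthetic_data import (
    SyntheticWorldSpec,
    generate_climate_grid,
    virtual_species_truth,
)


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def coarse_world():
    """Full-globe world at 4 degrees: fast enough for repeated fits."""
    spec = SyntheticWorldSpec(n_rows=45, n_cols=90, cell_size_deg=4.0, seed=42)
    return generate_climate_grid(spec)


@pytest.fixture(scope="session")
def coarse_truth(coarse_world):
    return virtual_species_truth(coarse_world)


@pytest.fixture(scope="session")
def default_world():
    """The default study world (90x180 cells at 2 degrees)."""
    return generate_climate_grid(SyntheticWorldSpec(seed=42))


def random_climate_grid(rng, n_rows=6, n_cols=8, cell_size_deg=4.0):
    """Small random-but-valid climate grid for property tests."""
    from pestclim.climate_io import ClimateGrid, GridGeometry

    geo = GridGeometry(n_rows=n_rows, n_cols=n_cols, cell_size_deg=cell_size_deg,
                       origin_lat=n_rows * cell_size_deg / 2.0)
    tmin = rng.uniform(-30, 25, size=(12, n_rows, n_cols))
    tmax = tmin + rng.uniform(2, 15, size=(12, n_rows, n_cols))
    rain = rng.uniform(0, 300, size=(12, n_rows, n_cols))
    rh09 = rng.uniform(30, 100, size=(12, n_rows, n_cols))
    rh15 = rng.uniform(20, 90, size=(12, n_rows, n_cols))
    return ClimateGrid(geometry=geo, tmin=tmin, tmax=tmax, rain=rain, rh09=rh09, rh15=rh15)
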