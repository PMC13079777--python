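import numpy as np
import pandas as pd
import pytest

from heatrisk.synthetic import (
    ClimateParams,
    GridSpec,
    StationSpec,
    make_meteo_grid,
    make_station_obs,
    make_wards,
)


def hourly_grid(nx=8, ny=8, start="2024-04-23", days=3):
    times = pd.date_range(start, periods=days * 24, freq="h")
    return GridSpec(nx=nx, ny=ny, cell_size=100.0, timestamps=times)


@pytest.fixture(scope="session")
def grid_small():
    return hourly_grid()


@pytest.fixture(scope="session")
def meteo_small(grid_small):
    return make_meteo_grid(grid_small, ClimateParams(), seed=7)


@pytest.fixture(scope="session")
def wards_small(grid_small):
    return make_wards(grid_small, n_wards=6, seed=7)


@pytest.fixture(scope="session")
def obs_noiseless(meteo_small):
    st = StationSpec(n_stations=5, obs_noise_sd=0.0)
    return make_station_obs(meteo_small, st, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
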