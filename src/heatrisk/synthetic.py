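"""Synthetic inputs for the heat-risk pipeline.

Generates gridded meteorology with a diurnal cycle and a coastal (cross-
domain) temperature gradient, a ward partition of the grid, a ward-level
socioeconomic indicator table drawn from a known latent-factor model, and
noisy station samples of the fields. Everything is deterministic given one
integer seed, so downstream recovery tests can compare against the known
generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

VULNERABILITY_INDICATORS = [
    "population_density",
    "household_density",
    "social_weaker_section",
]
EXPOSURE_INDICATORS = [
    "marginal_workers",
    "illiteracy",
    "dilapidated_household",
    "no_electric_connection",
    "untreated_water_quality",
    "distant_water_source",
]

# plausible ward-level magnitudes used to shift/scale the latent draws
_INDICATOR_SCALES = {
    "population_density": (25000.0, 9000.0),  # persons / km^2
    "household_density": (5500.0, 2000.0),  # households / km^2
    "social_weaker_section": (12.0, 5.0),  # % of population
    "marginal_workers": (6.0, 2.5),  # % of population
    "illiteracy": (12.0, 4.0),  # % of population
    "dilapidated_household": (4.0, 1.8),  # % of households
    "no_electric_connection": (3.0, 1.5),  # % of households
    "untreated_water_quality": (5.0, 2.0),  # % of households
    "distant_water_source": (4.0, 1.6),  # % of households
}

METEO_VARIABLES = ["ta", "rh", "wind", "swdown", "lwdown"]


@dataclass
class GridSpec:
    """Regular analysis grid with an hourly (or other) time axis."""

    nx: int
    ny: int
    cell_size: float = 333.0
    origin: tuple[float, float] = (0.0, 0.0)
    timestamps: pd.DatetimeIndex = field(default_factory=lambda: pd.DatetimeIndex([]))

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid needs nx, ny >= 2")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if len(self.timestamps) and not self.timestamps.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")
        if len(self.timestamps) != len(set(self.timestamps)):
            raise ValueError("timestamps must be strictly increasing (duplicates)")

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.nx) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.ny) + 0.5) * self.cell_size


@dataclass
class ClimateParams:
    """Climate of the synthetic fields.

    Temperatures in degC, humidity in %, wind in m/s, radiation in W/m^2.
    ``ta_gradient`` is the total west-to-east air-temperature increase across
    the domain (positive: east warmer, the coastal-city pattern). The solar
    cycle peaks at ``solar_peak_hour_utc`` so the hottest instant of the day
    is controllable. ``noise_sd`` scales the spatially smooth random texture
    added to every field.
    """

    ta_base: float = 29.5
    ta_diurnal_amplitude: float = 4.0
    ta_gradient: float = 3.0
    rh_base: float = 68.0
    rh_diurnal_amplitude: float = 12.0
    rh_gradient: float = -8.0
    wind_base: float = 2.5
    wind_diurnal_amplitude: float = 1.5
    swdown_max: float = 420.0
    lwdown_base: float = 414.0
    solar_peak_hour_utc: float = 7.0
    noise_sd: float = 0.5
    smoothness: float = 3.0  # gaussian-filter sigma, in cells

    def validate(self):
        if self.swdown_max < 0 or self.lwdown_base < 0:
            raise ValueError("radiation bases must be non-negative")
        if self.wind_base < 0:
            raise ValueError("wind_base must be non-negative")
        if not 0 <= self.rh_base <= 100:
            raise ValueError("rh_base must be in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class LatentFactorSpec:
    """Latent-factor model behind the indicator table.

    ``loading_matrix`` is indicators x factors; indicator values are
    factor scores @ loadings.T plus independent Gaussian noise, then mapped
    to plausible positive ranges per indicator.
    """

    loading_matrix: np.ndarray
    noise_sd: np.ndarray | float
    indicator_names: Sequence[str]

    def __post_init__(self):
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.loading_matrix.ndim != 2:
            raise ValueError("loading_matrix must be 2-D (indicators x factors)")
        if self.loading_matrix.shape[0] != len(self.indicator_names):
            raise ValueError("loading_matrix rows must match indicator_names")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.loading_matrix.shape[0],)
        ).copy()
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_factors(self) -> int:
        return self.loading_matrix.shape[1]

    def population_correlation(self) -> np.ndarray:
        """Correlation matrix implied by loadings + noise (orthonormal factors)."""
        cov = self.loading_matrix @ self.loading_matrix.T + np.diag(self.noise_sd**2)
        d = 1.0 / np.sqrt(np.diag(cov))
        return cov * np.outer(d, d)


@dataclass
class StationSpec:
    """Observation network sampling the gridded fields at point locations."""

    n_stations: int = 36
    obs_noise_sd: float = 0.5
    sampling_locations: np.ndarray | None = None  # (n, 2) x/y coordinates

    def __post_init__(self):
        if self.n_stations < 1:
            raise ValueError("need at least one station")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be non-negative")
        if self.sampling_locations is not None:
            self.sampling_locations = np.asarray(self.sampling_locations, dtype=float)


@dataclass
class WardMap:
    """Total disjoint partition of the grid cells into labelled wards."""

    labels: np.ndarray  # (ny, nx) int array of ward indices
    ward_ids: list[str]
    grid: GridSpec

    def __post_init__(self):
        if self.labels.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("labels shape must be (ny, nx)")

    @property
    def n_wards(self) -> int:
        return len(self.ward_ids)

    def cell_counts(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_wards)
        return pd.Series(counts, index=self.ward_ids, name="n_cells")

    def polygons(self) -> dict[str, object]:
        """Ward outlines as shapely geometries (union of member cell boxes)."""
        g = self.grid
        out = {}
        for k, wid in enumerate(self.ward_ids):
            rows, cols = np.nonzero(self.labels == k)
            cells = [
                box(
                    g.origin[0] + c * g.cell_size,
                    g.origin[1] + r * g.cell_size,
                    g.origin[0] + (c + 1) * g.cell_size,
                    g.origin[1] + (r + 1) * g.cell_size,
                )
                for r, c in zip(rows, cols)
            ]
            out[wid] = unary_union(cells)
        return out


def _smooth_noise(rng, shape, sigma):
    """Spatially smooth unit-variance noise (zero-mean, gaussian-filtered)."""
    raw = rng.standard_normal(shape)
    if sigma > 0:
        sm = gaussian_filter(raw, sigma=sigma, mode="reflect")
        sd = sm.std()
        if sd > 0:
            sm = sm / sd
        return sm
    return raw


def make_meteo_grid(
    spec: GridSpec, params: ClimateParams | None = None, seed: int = 0
) -> xr.Dataset:
    """Simulate gridded 2 m temperature, humidity, wind and radiation.

    Each variable combines a diurnal cycle, a fixed west-east gradient and a
    static spatially smooth random texture, emulating the structure of an
    urban-scale atmospheric simulation without any physics. RH is clipped to
    [0, 100] and wind to >= 0; shortwave radiation follows a clipped cosine
    day-arch peaking at ``params.solar_peak_hour_utc``.
    """
    params = params or ClimateParams()
    params.validate()
    if len(spec.timestamps) == 0:
        raise ValueError("grid spec has no timestamps")
    rng = np.random.default_rng(seed)

    nt, ny, nx = len(spec.timestamps), spec.ny, spec.nx
    hours = (
        spec.timestamps.hour.to_numpy()
        + spec.timestamps.minute.to_numpy() / 60.0
    )
    # 0 on the west edge, 1 on the east edge
    xg = np.linspace(0.0, 1.0, nx)[None, :] * np.ones((ny, 1))

    # diurnal phases: temperature lags solar peak slightly; RH is in antiphase
    solar = np.cos((hours - params.solar_peak_hour_utc) / 24.0 * 2 * np.pi)
    ta_cycle = params.ta_diurnal_amplitude * np.cos(
        (hours - params.solar_peak_hour_utc - 1.0) / 24.0 * 2 * np.pi
    )

    tex = {v: _smooth_noise(rng, (ny, nx), params.smoothness) for v in METEO_VARIABLES}

    rh_cycle = -params.rh_diurnal_amplitude * np.cos(
        (hours - params.solar_peak_hour_utc - 1.0) / 24.0 * 2 * np.pi
    )

    ta = (
        params.ta_base
        + ta_cycle[:, None, None]
        + params.ta_gradient * xg[None, :, :]
        + params.noise_sd * tex["ta"][None, :, :]
    )
    rh = np.clip(
        params.rh_base
        + rh_cycle[:, None, None]
        + params.rh_gradient * xg[None, :, :]
        + 2.0 * params.noise_sd * tex["rh"][None, :, :],
        0.0,
        100.0,
    )
    # sea-breeze-like daytime pickup in phase with the solar arch
    wind = np.clip(
        params.wind_base
        + params.wind_diurnal_amplitude * np.clip(solar, 0.0, None)[:, None, None]
        + 0.6 * params.noise_sd * tex["wind"][None, :, :]
        + np.zeros((nt, ny, nx)),
        0.0,
        None,
    )
    swdown = np.clip(
        params.swdown_max * np.clip(solar, 0.0, None)[:, None, None]
        + 10.0 * params.noise_sd * tex["swdown"][None, :, :] * (solar > 0)[:, None, None],
        0.0,
        None,
    )
    lwdown = np.clip(
        params.lwdown_base
        + 4.0 * (ta - params.ta_base)
        + 2.0 * params.noise_sd * tex["lwdown"][None, :, :],
        0.0,
        None,
    )

    coords = {"time": spec.timestamps, "y": spec.y_centers, "x": spec.x_centers}
    data = {
        "ta": (("time", "y", "x"), ta),
        "rh": (("time", "y", "x"), rh),
        "wind": (("time", "y", "x"), wind),
        "swdown": (("time", "y", "x"), swdown),
        "lwdown": (("time", "y", "x"), lwdown),
    }
    ds = xr.Dataset(data, coords=coords)
    ds["ta"].attrs.update(units="degC", long_name="2 m air temperature")
    ds["rh"].attrs.update(units="%", long_name="2 m relative humidity")
    ds["wind"].attrs.update(units="m s-1", long_name="10 m wind speed")
    ds["swdown"].attrs.update(units="W m-2", long_name="downward shortwave radiation")
    ds["lwdown"].attrs.update(units="W m-2", long_name="downward longwave radiation")
    ds.attrs.update(cell_size=spec.cell_size, origin_x=spec.origin[0], origin_y=spec.origin[1])
    return ds


def make_wards(spec: GridSpec, n_wards: int, seed: int = 0) -> WardMap:
    """Partition the grid into compact, contiguous-looking wards.

    Cell centroids are clustered with k-means, which yields irregular but
    compact blobs resembling municipal wards. Every cell belongs to exactly
    one ward and every ward is non-empty.
    """
    if n_wards < 1:
        raise ValueError("n_wards must be >= 1")
    if n_wards > spec.nx * spec.ny:
        raise ValueError("n_wards cannot exceed the number of grid cells")
    xs, ys = np.meshgrid(spec.x_centers, spec.y_centers)
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    if n_wards == spec.nx * spec.ny:
        raw = np.arange(len(pts))
    else:
        km = KMeans(n_clusters=n_wards, n_init=4, random_state=int(seed) % (2**31))
        raw = km.fit_predict(pts)
    # relabel deterministically: order clusters by (mean y, mean x)
    order = sorted(
        range(n_wards),
        key=lambda k: (pts[raw == k, 1].mean(), pts[raw == k, 0].mean()),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.vectorize(remap.get)(raw).reshape(spec.ny, spec.nx)
    width = max(2, len(str(n_wards)))
    ward_ids = [f"W{k + 1:0{width}d}" for k in range(n_wards)]
    wm = WardMap(labels=labels, ward_ids=ward_ids, grid=spec)
    if (wm.cell_counts() == 0).any():
        raise RuntimeError("ward partition produced an empty ward")
    return wm


def default_latent_spec(noise_sd: float = 0.3) -> LatentFactorSpec:
    """Three orthogonal factors behind the nine indicators.

    Factor 1 drives the vulnerability block (densities strongly, the
    socially-weaker share weakly and negatively); factors 2 and 3 drive the
    two exposure blocks (a social-deprivation block and a housing/services
    block), mirroring the two-component structure the exposure PCA is
    expected to recover.
    """
    names = VULNERABILITY_INDICATORS + EXPOSURE_INDICATORS
    L = np.zeros((9, 3))
    L[0, 0] = 0.95  # population density
    L[1, 0] = 0.95  # household density
    L[2, 0] = -0.50  # social weaker section
    L[3, 1] = 0.75  # marginal workers
    L[4, 1] = 0.85  # illiteracy
    L[8, 1] = 0.80  # distant water source
    L[5, 2] = 0.80  # dilapidated household
    L[6, 2] = 0.70  # no electric connection
    L[7, 2] = 0.85  # untreated water quality
    return LatentFactorSpec(loading_matrix=L, noise_sd=noise_sd, indicator_names=names)


@dataclass
class IndicatorTable:
    """Ward x indicator matrix with per-indicator orientation metadata."""

    values: pd.DataFrame
    orientation: dict[str, int]
    metadata: dict | None = None

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.orientation)
        if missing:
            raise ValueError(f"orientation missing for columns: {sorted(missing)}")


def make_indicators(
    n_wards: int, lf: LatentFactorSpec | None = None, seed: int = 0
) -> IndicatorTable:
    """Draw a ward indicator table from the latent-factor model.

    Values are factor scores x loadings' + noise, then affinely mapped into
    plausible positive ranges per indicator (affine maps leave correlations
    untouched). The generating loadings and scores are kept in ``metadata``
    so recovery tests can compare estimates with truth. All indicators carry
    a positive functional relationship to their index.
    """
    lf = lf or default_latent_spec()
    if n_wards < 1:
        raise ValueError("need at least 1 ward")
    p = len(lf.indicator_names)
    degenerate = bool(
        np.all(lf.noise_sd == 0) and np.linalg.matrix_rank(lf.loading_matrix) < p
    )
    if degenerate:
        logger.warning(
            "rank-deficient loading matrix with zero noise: the indicator "
            "correlation matrix will be singular downstream"
        )
    rng = np.random.default_rng(seed)
    scores = rng.standard_normal((n_wards, lf.n_factors))
    noise = rng.standard_normal((n_wards, p)) * lf.noise_sd
    raw = scores @ lf.loading_matrix.T + noise

    width = max(2, len(str(n_wards)))
    ward_ids = [f"W{k + 1:0{width}d}" for k in range(n_wards)]
    df = pd.DataFrame(raw, index=pd.Index(ward_ids, name="ward_id"),
                      columns=list(lf.indicator_names))
    for name in df.columns:
        mean, sd = _INDICATOR_SCALES.get(name, (10.0, 3.0))
        col = df[name]
        colsd = col.std(ddof=1)
        z = (col - col.mean()) / colsd if colsd > 0 else col * 0.0
        df[name] = (mean + sd * z).clip(lower=0.0)
    orientation = {name: +1 for name in df.columns}
    meta = {
        "loading_matrix": lf.loading_matrix.copy(),
        "noise_sd": lf.noise_sd.copy(),
        "factor_scores": scores,
        "population_correlation": lf.population_correlation(),
        "degenerate": degenerate,
        "seed": seed,
    }
    return IndicatorTable(values=df, orientation=orientation, metadata=meta)


def _nearest_cell(spec_like: xr.Dataset, sx, sy):
    """Row/col of the grid cell containing (or nearest to) a point."""
    x = spec_like["x"].values
    y = spec_like["y"].values
    cell = float(spec_like.attrs.get("cell_size", x[1] - x[0]))
    ox = float(spec_like.attrs.get("origin_x", x[0] - cell / 2))
    oy = float(spec_like.attrs.get("origin_y", y[0] - cell / 2))
    col = int(np.floor((sx - ox) / cell))
    row = int(np.floor((sy - oy) / cell))
    if not (0 <= col < x.size and 0 <= row < y.size):
        raise ValueError(f"station at ({sx}, {sy}) lies outside the grid")
    return row, col


def make_station_obs(
    field: xr.Dataset, st: StationSpec, seed: int = 0
) -> pd.DataFrame:
    """Sample Ta/RH/wind at station locations with additive Gaussian noise.

    Stations read the nearest grid cell (no interpolation). Returns a long
    table with columns station_id, time, variable, value, x, y.
    """
    rng = np.random.default_rng(seed)
    x = field["x"].values
    y = field["y"].values
    cell = float(field.attrs.get("cell_size", x[1] - x[0]))
    ox = float(field.attrs.get("origin_x", x[0] - cell / 2))
    oy = float(field.attrs.get("origin_y", y[0] - cell / 2))
    if st.sampling_locations is None:
        locs = np.column_stack(
            [
                rng.uniform(ox, ox + cell * x.size, st.n_stations),
                rng.uniform(oy, oy + cell * y.size, st.n_stations),
            ]
        )
    else:
        locs = st.sampling_locations
        if locs.shape[0] != st.n_stations:
            raise ValueError("sampling_locations rows must equal n_stations")

    times = pd.DatetimeIndex(field["time"].values)
    rows = []
    for si in range(st.n_stations):
        sx, sy = locs[si]
        r, c = _nearest_cell(field, sx, sy)
        sid = f"S{si + 1:02d}"
        for var in ("ta", "rh", "wind"):
            truth = field[var].values[:, r, c]
            obs = truth + rng.normal(0.0, st.obs_noise_sd, truth.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "station_id": sid,
                        "time": times,
                        "variable": var,
                        "value": obs,
                        "x": sx,
                        "y": sy,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def select_analysis_times(
    field: xr.Dataset,
    spinup_hours: int = 24,
    segment_days: int = 3,
    analysis_hour_utc: int | None = 7,
) -> xr.Dataset:
    """Drop per-segment spin-up hours, then keep one analysis hour per day.

    The time axis is split into consecutive ``segment_days``-long segments
    starting at the first timestamp; the first ``spinup_hours`` of each
    segment are discarded (simulation spin-up), and only instants at
    ``analysis_hour_utc`` are retained (pass None to keep all hours).
    """
    times = pd.DatetimeIndex(field["time"].values)
    if len(times) == 0:
        raise ValueError("field has no timestamps")
    hours_since_start = (times - times[0]) / pd.Timedelta(hours=1)
    seg_len = segment_days * 24
    within = np.asarray(hours_since_start) % seg_len
    keep = within >= spinup_hours
    if analysis_hour_utc is not None:
        keep &= times.hour == analysis_hour_utc
    if not keep.any():
        raise ValueError("time selection is empty")
    return field.isel(time=np.nonzero(keep)[0])
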