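"""End-to-end orchestration: simulate -> UTCI -> hazard -> indices -> risk.

Each stage is file-driven: it reads the products of earlier stages from the
run directory and writes its own, so the CLI subcommands and ``run_pipeline``
produce identical artifacts. All CSV/JSON products are written with fixed
float formatting and sorted JSON keys, making repeated runs with the same
configuration and seed byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

import heatrisk
from heatrisk import io
from heatrisk.composite import build_composite_index
from heatrisk.config import RunConfig
from heatrisk.hazard import ward_hazard_table
from heatrisk.metrics import station_validate
from heatrisk.risk import hsri, risk_classify, summary_report
from heatrisk.synthetic import (
    StationSpec,
    VULNERABILITY_INDICATORS,
    default_latent_spec,
    make_indicators,
    make_meteo_grid,
    make_station_obs,
    make_wards,
    select_analysis_times,
)
from heatrisk.utci import utci_field

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(cfg: RunConfig) -> None:
    """Generate meteorology, wards, indicators and station observations."""
    out = _outdir(cfg)
    spec = cfg.grid_spec()
    meteo = make_meteo_grid(spec, cfg.climate_params(), seed=cfg.seed)
    wards = make_wards(spec, cfg.n_wards, seed=cfg.seed + 1)
    table = make_indicators(
        cfg.n_wards, default_latent_spec(cfg.indicator_noise_sd), seed=cfg.seed + 2
    )
    obs = make_station_obs(
        meteo,
        StationSpec(n_stations=cfg.n_stations, obs_noise_sd=cfg.obs_noise_sd),
        seed=cfg.seed + 3,
    )
    io.write_meteo_netcdf(meteo, out / "meteo.nc")
    io.wards_to_geojson(wards, out / "wards.geojson")
    io.write_table(table.values, out / "indicators.csv")
    obs.to_csv(out / "stations.csv", index=False, float_format="%.10g")
    logger.info("simulate: %d timestamps, %d wards, %d stations",
                len(spec.timestamps), cfg.n_wards, cfg.n_stations)


def stage_validate(cfg: RunConfig) -> pd.DataFrame:
    """Compare the simulated fields with the station observations."""
    out = _outdir(cfg)
    meteo = io.read_meteo_netcdf(out / "meteo.nc")
    obs = pd.read_csv(out / "stations.csv", parse_dates=["time"])
    metrics = station_validate(meteo, obs)
    io.write_table(metrics, out / "validation_metrics.csv")
    return metrics


def stage_utci(cfg: RunConfig) -> None:
    """Select analysis instants and compute the UTCI grid."""
    out = _outdir(cfg)
    meteo = io.read_meteo_netcdf(out / "meteo.nc")
    selected = select_analysis_times(
        meteo, cfg.spinup_hours, cfg.segment_days, cfg.analysis_hour_utc
    )
    utci = utci_field(selected, albedo=cfg.albedo, emissivity=cfg.emissivity)
    io.dataset_to_long_csv(utci, out / "utci_grid.csv", variables=["utci", "tmrt"])
    logger.info("utci: %d analysis instants", utci.sizes["time"])


def stage_hazard(cfg: RunConfig) -> pd.DataFrame:
    """Ward-average UTCI, hazard index and category."""
    out = _outdir(cfg)
    utci = io.dataset_from_long_csv(out / "utci_grid.csv")
    wards = io.wards_from_geojson(out / "wards.geojson")
    hz = ward_hazard_table(utci, wards)
    io.write_table(hz, out / "hazard.csv")
    return hz


def stage_indices(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vulnerability and exposure indices with their PCA reports."""
    out = _outdir(cfg)
    table = pd.read_csv(out / "indicators.csv", index_col="ward_id")
    vuln_cols = [c for c in table.columns if c in VULNERABILITY_INDICATORS]
    expo_cols = [c for c in table.columns if c not in VULNERABILITY_INDICATORS]
    vi, vi_pca = build_composite_index(table[vuln_cols], name="vulnerability")
    ei, ei_pca = build_composite_index(table[expo_cols], name="exposure")
    io.write_table(vi, out / "vulnerability.csv")
    io.write_table(ei, out / "exposure.csv")
    io.write_json(vi_pca.report(), out / "pca_vulnerability.json")
    io.write_json(ei_pca.report(), out / "pca_exposure.json")
    return vi, ei


def stage_risk(cfg: RunConfig) -> pd.DataFrame:
    """Combine the indices, classify, and write the risk products."""
    out = _outdir(cfg)
    hz = pd.read_csv(out / "hazard.csv", index_col="ward_id")
    vi = pd.read_csv(out / "vulnerability.csv", index_col="ward_id")
    ei = pd.read_csv(out / "exposure.csv", index_col="ward_id")
    risk = pd.DataFrame(
        {"HI": hz["HI"], "VI": vi["value"], "EI": ei["value"]}
    )
    risk["HSRI"] = hsri(risk["HI"], risk["VI"], risk["EI"])
    labels, shares = risk_classify(risk["HSRI"])
    risk["category"] = labels
    io.write_table(risk, out / "risk.csv")
    io.write_json(summary_report(risk), out / "risk_summary.json")
    wards = io.wards_from_geojson(out / "wards.geojson")
    io.wards_to_geojson(wards, out / "risk.geojson", properties=risk)
    logger.info("risk shares:\n%s", shares)
    return risk


def write_manifest(cfg: RunConfig) -> None:
    import numpy as np
    import xarray as xr

    manifest = {
        "config": cfg.science_dict(),
        "config_sha256": cfg.hash(),
        "seed": cfg.seed,
        "versions": {
            "heatrisk": heatrisk.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "xarray": xr.__version__,
        },
    }
    io.write_json(manifest, _outdir(cfg) / "manifest.json")


_STAGES = (
    ("simulate", stage_simulate),
    ("validate", stage_validate),
    ("utci", stage_utci),
    ("hazard", stage_hazard),
    ("indices", stage_indices),
    ("risk", stage_risk),
)


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Run every stage in order; returns the per-ward risk table."""
    result = None
    for name, fn in _STAGES:
        try:
            out = fn(cfg)
        except Exception as e:
            raise PipelineStageError(name, e) from e
        if name == "risk":
            result = out
    write_manifest(cfg)
    return result
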