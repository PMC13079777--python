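"""Run configuration for the end-to-end pipeline.

Defaults mirror the study design the pipeline emulates: an April-May hot
spell simulated as five 3-day segments with the first 24 h of each segment
discarded as spin-up, analysis at 0700 UTC (early-afternoon local time at
the study longitude, when UTCI peaks), 24 wards, 36 stations, and
five-level SD classification.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from heatrisk.synthetic import ClimateParams, GridSpec


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results/run"
    # grid
    nx: int = 24
    ny: int = 24
    cell_size: float = 333.0
    start: str = "2024-04-23"
    n_days: int = 15
    freq_hours: int = 1
    # synthesis
    climate: dict = field(default_factory=dict)  # ClimateParams overrides
    n_wards: int = 24
    n_stations: int = 36
    obs_noise_sd: float = 0.5
    indicator_noise_sd: float = 0.3
    # time selection
    spinup_hours: int = 24
    segment_days: int = 3
    analysis_hour_utc: int = 7
    # radiant-temperature surface parameters
    albedo: float = 0.3
    emissivity: float = 0.97

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def grid_spec(self) -> GridSpec:
        times = pd.date_range(
            self.start, periods=self.n_days * 24 // self.freq_hours,
            freq=f"{self.freq_hours}h",
        )
        return GridSpec(
            nx=self.nx, ny=self.ny, cell_size=self.cell_size, timestamps=times
        )

    def climate_params(self) -> ClimateParams:
        return ClimateParams(**self.climate)

    def to_dict(self) -> dict:
        return asdict(self)

    def science_dict(self) -> dict:
        """Config without the output location (what the results depend on)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def hash(self) -> str:
        blob = json.dumps(self.science_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
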