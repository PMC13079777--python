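#!/usr/bin/env python
"""Generate the study inputs: gridded meteorology over an April-May hot
spell (five 3-day segments, hourly), a 24-ward partition of the domain, the
ward socioeconomic indicator table and 36 noisy station records.

Writes meteo.nc, wards.geojson, indicators.csv and stations.csv under the
run directory.
"""

import argparse

from heatrisk import io
from heatrisk.config import RunConfig
from heatrisk.pipeline import stage_simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/analysis")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=args.out)
    stage_simulate(cfg)

    meteo = io.read_meteo_netcdf(f"{args.out}/meteo.nc")
    print(f"simulated {meteo.sizes['time']} hourly instants on a "
          f"{cfg.ny}x{cfg.nx} grid ({cfg.cell_size:.0f} m cells)")
    print(f"2 m temperature range: {float(meteo['ta'].min()):.1f} to "
          f"{float(meteo['ta'].max()):.1f} degC; "
          f"RH {float(meteo['rh'].min()):.0f}-{float(meteo['rh'].max()):.0f} %")
    print(f"{cfg.n_wards} wards, {cfg.n_stations} stations -> {args.out}")


if __name__ == "__main__":
    main()
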