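"""Model-validation statistics for simulated fields vs. station observations.

Pearson correlation (PCC), root-mean-square error (RMSE), mean absolute
error (MAE) and Willmott's classical index of agreement (IoA):

    IoA = 1 - sum (O - P)^2 / sum (|P - Obar| + |O - Obar|)^2

Observations and predictions are paired by station location (nearest grid
cell) and exact timestamp after rounding to the hour; metrics are pooled
across stations by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

logger = logging.getLogger(__name__)


def _pair(observed, predicted):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have the same length")
    if o.size < 2:
        raise ValueError("need at least 2 pairs")
    return o, p


def pcc(observed, predicted) -> float:
    """Pearson correlation; NaN if either series is constant."""
    o, p = _pair(observed, predicted)
    if o.std() == 0 or p.std() == 0:
        return float("nan")
    return float(stats.pearsonr(o, p).statistic)


def rmse(observed, predicted) -> float:
    o, p = _pair(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def mae(observed, predicted) -> float:
    o, p = _pair(observed, predicted)
    return float(np.mean(np.abs(o - p)))


def ioa(observed, predicted) -> float:
    """Willmott's index of agreement in [0, 1]; 1 is perfect."""
    o, p = _pair(observed, predicted)
    num = np.sum((o - p) ** 2)
    obar = o.mean()
    den = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    if den == 0:
        raise ValueError("IoA undefined: all values equal the observed mean")
    return float(1.0 - num / den)


def _metric_row(o, p) -> dict:
    return {
        "n": int(len(o)),
        "pcc": pcc(o, p),
        "rmse": rmse(o, p),
        "mae": mae(o, p),
        "ioa": ioa(o, p),
    }


def station_validate(
    field: xr.Dataset, obs: pd.DataFrame, per_station: bool = False
) -> pd.DataFrame:
    """PCC/RMSE/MAE/IoA per variable, pooling all stations.

    ``obs`` is the long station table (station_id, time, variable, value,
    x, y). Each record is paired with the field value of the nearest grid
    cell at the matching hour-rounded timestamp; unmatched records are
    dropped and counted in the log. Set ``per_station`` for a per-station
    breakdown instead of pooled metrics.
    """
    from heatrisk.synthetic import _nearest_cell

    field_times = pd.DatetimeIndex(field["time"].values)
    time_pos = {t: i for i, t in enumerate(field_times)}
    obs = obs.copy()
    obs["time"] = pd.DatetimeIndex(obs["time"]).round("h")

    cells = {
        sid: _nearest_cell(field, g["x"].iloc[0], g["y"].iloc[0])
        for sid, g in obs.groupby("station_id")
    }

    dropped = 0
    records = []
    for (sid, var), g in obs.groupby(["station_id", "variable"]):
        if var not in field:
            dropped += len(g)
            continue
        r, c = cells[sid]
        series = field[var].values[:, r, c]
        tidx = g["time"].map(time_pos)
        ok = tidx.notna()
        dropped += int((~ok).sum())
        if not ok.any():
            continue
        records.append(
            pd.DataFrame(
                {
                    "station_id": sid,
                    "variable": var,
                    "observed": g.loc[ok, "value"].to_numpy(),
                    "predicted": series[tidx[ok].astype(int)],
                }
            )
        )
    if dropped:
        logger.info("station_validate: dropped %d unmatched records", dropped)
    if not records:
        raise ValueError("no overlapping timestamps between field and observations")
    paired = pd.concat(records, ignore_index=True)

    keys = ["variable", "station_id"] if per_station else ["variable"]
    rows = []
    for key, g in paired.groupby(keys):
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(_metric_row(g["observed"].to_numpy(), g["predicted"].to_numpy()))
        rows.append(row)
    return pd.DataFrame(rows).set_index(keys)
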