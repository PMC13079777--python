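"""Ward-level heat hazard index from gridded UTCI.

The four heat-stress bands of the UTCI assessment scale are re-indexed onto
a common [0, 1] scale, piecewise-linearly within each band, so the hazard
index is commensurable with the vulnerability and exposure indices:

    <= 9 degC -> 0;  9-26 -> 0-0.25;  26-32 -> 0.25-0.50;
    32-38 -> 0.50-0.75;  38-46 -> 0.75-1.00;  > 46 -> 1.00

The cold side is collapsed to zero: this is a heat-stress index. Ward values
are unweighted arithmetic means of member grid cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from heatrisk.categories import sd_classify
from heatrisk.synthetic import WardMap

_BAND_UTCI = np.array([9.0, 26.0, 32.0, 38.0, 46.0])
_BAND_HI = np.array([0.0, 0.25, 0.50, 0.75, 1.00])


def normalize_utci(utci) -> np.ndarray:
    """Map UTCI (degC) onto the [0, 1] hazard scale (total, monotone map)."""
    return np.interp(np.asarray(utci, dtype=float), _BAND_UTCI, _BAND_HI)


def ward_aggregate(values, wards: WardMap) -> pd.Series:
    """Unweighted mean of member-cell values per ward.

    ``values`` is a (ny, nx) array or DataArray matching the ward grid.
    """
    arr = values.values if hasattr(values, "values") else np.asarray(values)
    if arr.shape != wards.labels.shape:
        raise ValueError(
            f"field shape {arr.shape} does not match ward grid {wards.labels.shape}"
        )
    counts = np.bincount(wards.labels.ravel(), minlength=wards.n_wards)
    if (counts == 0).any():
        raise ValueError("every ward must contain at least one grid cell")
    sums = np.bincount(
        wards.labels.ravel(), weights=arr.ravel(), minlength=wards.n_wards
    )
    return pd.Series(
        sums / counts, index=pd.Index(wards.ward_ids, name="ward_id"), name="mean"
    )


def hazard_categories(hi_values, ddof: int = 1) -> pd.Series:
    """Five-level labels for ward hazard values (shared SD-bin scheme)."""
    return sd_classify(hi_values, ddof=ddof)


def ward_hazard_table(utci_grid: xr.Dataset | xr.DataArray, wards: WardMap) -> pd.DataFrame:
    """Per-ward mean UTCI, hazard index and category.

    A time axis, if present, is averaged first (the analysis instants are
    assumed already selected), then cells are averaged within wards.
    """
    da = utci_grid["utci"] if isinstance(utci_grid, xr.Dataset) else utci_grid
    if "time" in da.dims:
        da = da.mean("time")
    mean_utci = ward_aggregate(da, wards).rename("mean_utci")
    hi = pd.Series(
        normalize_utci(mean_utci.values), index=mean_utci.index, name="HI"
    )
    out = pd.concat([mean_utci, hi], axis=1)
    out["category"] = hazard_categories(out["HI"])
    return out
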