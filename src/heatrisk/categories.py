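"""Five-level standard-deviation classification shared by all indices.

Ward index values are z-scored and binned at -1.5, -0.5, +0.5 and +1.5
standard deviations from the mean. Bins are left-open / right-closed, so a
ward sitting exactly on a boundary falls into the lower class. A constant
vector has zero variance and every ward is labelled "Moderate".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CATEGORY_LABELS = ["Lowest", "Low", "Moderate", "High", "Highest"]

_BIN_EDGES = np.array([-1.5, -0.5, 0.5, 1.5])


def sd_classify(values, ddof: int = 1) -> pd.Series:
    """Label each value by its z-score bin.

    Parameters
    ----------
    values : array-like or pandas Series
        Index values across wards (at least 2).
    ddof : int
        Delta degrees of freedom for the standard deviation; 1 (sample SD)
        by default.

    Returns
    -------
    pandas.Series of labels from :data:`CATEGORY_LABELS`, index-aligned
    with the input when it is a Series.
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise ValueError("classification needs at least 2 values")
    sd = s.std(ddof=ddof)
    if not np.isfinite(sd) or sd == 0:
        labels = np.full(len(s), "Moderate", dtype=object)
    else:
        z = (s - s.mean()) / sd
        # side="left": z exactly on an edge goes to the lower class
        idx = np.searchsorted(_BIN_EDGES, z.to_numpy(), side="left")
        labels = np.array(CATEGORY_LABELS, dtype=object)[idx]
    return pd.Series(labels, index=s.index, name="category")


def category_shares(labels) -> pd.DataFrame:
    """Count and percentage share per category, zeros for empty classes.

    Shares are count / total x 100, rounded to one decimal.
    """
    s = pd.Series(labels)
    counts = s.value_counts().reindex(CATEGORY_LABELS, fill_value=0)
    shares = (counts / counts.sum() * 100).round(1)
    return pd.DataFrame({"count": counts.astype(int), "share_pct": shares})
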