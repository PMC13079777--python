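"""Heat Stress Risk Index: HSRI = HI x VI x EI.

The three [0, 1] ward indices multiply elementwise; the raw product is not
re-normalized before classification, so a ward scoring low on any one
dimension is pulled toward low risk (the product is bounded above by the
smallest factor).
"""

from __future__ import annotations

import pandas as pd

from heatrisk.categories import category_shares, sd_classify


def hsri(hi: pd.Series, vi: pd.Series, ei: pd.Series) -> pd.Series:
    """Elementwise product of the hazard, vulnerability and exposure indices."""
    hi, vi, ei = pd.Series(hi, dtype=float), pd.Series(vi, dtype=float), pd.Series(ei, dtype=float)
    if not (hi.index.equals(vi.index) and hi.index.equals(ei.index)):
        raise ValueError("HI, VI and EI must be aligned on the same ward set")
    for name, s in (("HI", hi), ("VI", vi), ("EI", ei)):
        if (s < 0).any() or (s > 1).any():
            raise ValueError(f"{name} must lie on [0, 1]")
    out = hi * vi * ei
    out.name = "HSRI"
    return out


def risk_classify(values, ddof: int = 1) -> tuple[pd.Series, pd.DataFrame]:
    """SD-bin labels plus per-category counts and percentage shares."""
    labels = sd_classify(values, ddof=ddof)
    return labels, category_shares(labels)


def summary_report(ward_risk: pd.DataFrame) -> dict:
    """Per-ward table and per-category roll-up as a JSON-ready mapping.

    ``ward_risk`` needs a ``category`` column; all columns are passed through
    to the per-ward records.
    """
    shares = category_shares(ward_risk["category"])
    return {
        "n_wards": int(len(ward_risk)),
        "wards": ward_risk.round(6).reset_index().to_dict(orient="records"),
        "categories": {
            cat: {"count": int(row["count"]), "share_pct": float(row["share_pct"])}
            for cat, row in shares.iterrows()
        },
    }
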