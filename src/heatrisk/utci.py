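"""Universal Thermal Climate Index (UTCI) engine.

UTCI expresses the thermal stress of an outdoor environment as an
equivalent temperature (degC). The operational form used here is the
COST Action 730 six-order polynomial approximation in air temperature Ta,
the mean-radiant-temperature excess (Tmrt - Ta), 10 m wind speed va and
water vapour pressure pa. The 210 polynomial coefficients ship as a
machine-readable CSV keyed by exponent tuple, guarded by a checksum
(hand-transcribed coefficient tables are error-prone).

Validity envelope of the approximation: Ta in [-50, 50] degC, va in
[0.5, 17] m/s, Tmrt - Ta in [-30, 70] K, pa <= 50 hPa. Wind below 0.5 m/s
is clamped up to 0.5 (standard operational handling of calm air); the
radiant excess and vapour pressure are clamped into the envelope with the
validity flag set; Ta outside [-50, 50] or wind above 17 m/s is rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

SIGMA = 5.670374419e-8  # Stefan-Boltzmann constant, W m-2 K-4

_COEF_SHA256 = "d823eeb43a0b05a3b626d317d0e4a4d51f6cf7d6ffcc29d2e5e2c05d204ada76"

# 10-class UTCI assessment scale; upper bound inclusive, lower bound open
UTCI_STRESS_CLASSES = [
    (-40.0, "Extreme cold stress"),
    (-27.0, "Very strong cold stress"),
    (-13.0, "Strong cold stress"),
    (0.0, "Moderate cold stress"),
    (9.0, "Slight cold stress"),
    (26.0, "No thermal stress"),
    (32.0, "Moderate heat stress"),
    (38.0, "Strong heat stress"),
    (46.0, "Very strong heat stress"),
    (np.inf, "Extreme heat stress"),
]

_coef_cache: tuple[np.ndarray, np.ndarray] | None = None


class UTCIDomainError(ValueError):
    """Inputs fall outside the polynomial's clamping policy."""


def load_coefficients() -> pd.DataFrame:
    """Packaged polynomial coefficient table, checksum-verified."""
    ref = resources.files("heatrisk.data").joinpath(
        "utci_polynomial_coefficients.csv"
    )
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _COEF_SHA256:
        raise RuntimeError(
            "UTCI coefficient table failed its checksum; the packaged file "
            "was modified"
        )
    from io import StringIO

    tab = pd.read_csv(StringIO(text))
    if len(tab) != 210:
        raise RuntimeError("UTCI coefficient table must have 210 terms")
    return tab


def _coefficients() -> tuple[np.ndarray, np.ndarray]:
    global _coef_cache
    if _coef_cache is None:
        tab = load_coefficients()
        _coef_cache = (
            tab[["ta_pow", "dtmrt_pow", "va_pow", "pa_pow"]].to_numpy(int),
            tab["coefficient"].to_numpy(float),
        )
    return _coef_cache


def saturation_vapor_pressure(ta) -> np.ndarray:
    """Saturation vapour pressure over water (hPa) at air temperature ta (degC).

    Hardy's ITS-90 formulation, the one the UTCI operational software is
    calibrated with.
    """
    g = (
        -2836.5744,
        -6028.076559,
        19.54263612,
        -0.02737830188,
        1.6261698e-05,
        7.0229056e-10,
        -1.8680009e-13,
    )
    tk = np.asarray(ta, dtype=float) + 273.15
    es = 2.7150305 * np.log(tk)
    for i, gi in enumerate(g):
        es = es + gi * tk ** (i - 2)
    return np.exp(es) * 0.01  # Pa -> hPa


def vapor_pressure(ta, rh) -> np.ndarray:
    """Water vapour pressure (hPa) from air temperature (degC) and RH (%)."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity must be within [0, 100] %")
    return rh / 100.0 * saturation_vapor_pressure(ta)


def mean_radiant_temperature(
    swdown, lwdown, albedo: float = 0.3, emissivity: float = 0.97
) -> np.ndarray:
    """Mean radiant temperature (degC) from a two-stream flux budget.

    Inverts the Stefan-Boltzmann law for the radiant flux absorbed by a
    reference body exposed to downward shortwave ``swdown`` and longwave
    ``lwdown`` (W/m^2):

        sigma * Tmrt^4 = [eps * L + (1 - albedo) * S] / eps

    With zero shortwave and isotropic longwave L = sigma*T^4 this reduces to
    Tmrt = T (blackbody identity). Directional six-flux weightings can be
    emulated by pre-combining fluxes before the call; albedo and emissivity
    are configurable.
    """
    sw = np.asarray(swdown, dtype=float)
    lw = np.asarray(lwdown, dtype=float)
    if np.any(sw < 0) or np.any(lw < 0):
        raise ValueError("radiative fluxes must be non-negative")
    if not 0 <= albedo < 1 or not 0 < emissivity <= 1:
        raise ValueError("need 0 <= albedo < 1 and 0 < emissivity <= 1")
    absorbed = emissivity * lw + (1.0 - albedo) * sw
    tmrt_k = (absorbed / (emissivity * SIGMA)) ** 0.25
    return tmrt_k - 273.15


def utci(ta, tmrt, va, pa, clamp: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """UTCI (degC) from Ta (degC), Tmrt (degC), wind (m/s), pa (hPa).

    Returns ``(utci, clamped)`` arrays; ``clamped`` flags elements whose
    inputs were pulled back into the validity envelope. With ``clamp=False``
    any out-of-envelope element raises :class:`UTCIDomainError`.
    """
    ta = np.asarray(ta, dtype=float)
    tmrt = np.asarray(tmrt, dtype=float)
    va = np.asarray(va, dtype=float)
    pa = np.asarray(pa, dtype=float)
    ta, tmrt, va, pa = np.broadcast_arrays(ta, tmrt, va, pa)

    if np.any(ta < -50.0) or np.any(ta > 50.0):
        raise UTCIDomainError("air temperature outside [-50, 50] degC")
    if np.any(va > 17.0):
        raise UTCIDomainError("wind speed above 17 m/s")
    if np.any(va < 0.0):
        raise ValueError("wind speed must be non-negative")
    if np.any(pa < 0.0):
        raise ValueError("vapour pressure must be non-negative")

    d = tmrt - ta
    clamped = (va < 0.5) | (d < -30.0) | (d > 70.0) | (pa > 50.0)
    if not clamp and clamped.any():
        raise UTCIDomainError("inputs outside the polynomial validity envelope")
    va_c = np.clip(va, 0.5, 17.0)
    d_c = np.clip(d, -30.0, 70.0)
    pa_kpa = np.clip(pa, 0.0, 50.0) / 10.0

    exps, coefs = _coefficients()
    offset = np.zeros(ta.shape, dtype=float)
    for (i, j, k, l), c in zip(exps, coefs):
        term = c
        if i:
            term = term * ta**i
        if j:
            term = term * d_c**j
        if k:
            term = term * va_c**k
        if l:
            term = term * pa_kpa**l
        offset = offset + term
    return ta + offset, clamped


def categorize(value) -> np.ndarray:
    """Stress class of a UTCI value per the 10-class assessment scale.

    Bands are closed on their upper bound: exactly 46 degC is still "Very
    strong heat stress", anything above is "Extreme heat stress".
    """
    v = np.asarray(value, dtype=float)
    bounds = np.array([b for b, _ in UTCI_STRESS_CLASSES[:-1]])
    labels = np.array([lab for _, lab in UTCI_STRESS_CLASSES], dtype=object)
    idx = np.searchsorted(bounds, v, side="left")
    out = labels[idx]
    return out if v.ndim else out.item() if isinstance(out, np.ndarray) else out


@dataclass
class UTCIValue:
    """Scalar UTCI result with its stress class and clamping flag."""

    utci: float
    category: str
    clamped: bool


def utci_value(ta: float, tmrt: float, va: float, pa: float) -> UTCIValue:
    """Scalar convenience wrapper around :func:`utci` and :func:`categorize`."""
    u, flag = utci(ta, tmrt, va, pa)
    u = float(u)
    return UTCIValue(utci=u, category=str(categorize(u)), clamped=bool(flag))


def utci_field(
    meteo: xr.Dataset, albedo: float = 0.3, emissivity: float = 0.97
) -> xr.Dataset:
    """Element-wise UTCI over a gridded meteorology dataset.

    Requires variables ``ta`` (degC), ``rh`` (%), ``wind`` (m/s) and either
    ``tmrt`` (degC) or the radiation pair ``swdown``/``lwdown`` (W/m^2) from
    which Tmrt is derived. Adds ``utci`` and ``tmrt`` variables plus a
    ``utci_clamped`` flag field.
    """
    for var in ("ta", "rh", "wind"):
        if var not in meteo:
            raise KeyError(f"meteo dataset is missing required variable '{var}'")
    if "tmrt" in meteo:
        tmrt = meteo["tmrt"].values
    elif "swdown" in meteo and "lwdown" in meteo:
        tmrt = mean_radiant_temperature(
            meteo["swdown"].values, meteo["lwdown"].values, albedo, emissivity
        )
    else:
        raise KeyError(
            "meteo dataset needs 'tmrt' or the radiation pair 'swdown'/'lwdown'"
        )
    pa = vapor_pressure(meteo["ta"].values, meteo["rh"].values)
    u, flag = utci(meteo["ta"].values, tmrt, meteo["wind"].values, pa)
    out = meteo.copy()
    dims = meteo["ta"].dims
    out["tmrt"] = (dims, np.broadcast_to(tmrt, meteo["ta"].shape).copy())
    out["utci"] = (dims, u)
    out["utci_clamped"] = (dims, flag)
    out["utci"].attrs.update(units="degC", long_name="Universal Thermal Climate Index")
    out["tmrt"].attrs.update(units="degC", long_name="mean radiant temperature")
    return out
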