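"""PCA-weighted composite indices for vulnerability and exposure.

Ward indicators are min-max normalized with their functional orientation
(Eqs. of the min-max scheme), z-standardized, checked for factorability
(KMO sampling adequacy and Bartlett's sphericity test), and reduced by PCA
on the correlation matrix. Components with eigenvalue > 1 are retained
(Kaiser criterion), varimax-rotated when there are at least two, scored by
the regression method, weighted by their variance ratios and summed; the
resulting composite is min-max rescaled to [0, 1] and classified into five
standard-deviation categories.

Conventions follow the SPSS defaults the field typically uses: sample
standard deviations, Kaiser row-normalization inside varimax, and
regression factor scores Z R^-1 Lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from heatrisk.categories import sd_classify

logger = logging.getLogger(__name__)

KMO_ACCEPTABLE = 0.5


class DegenerateColumnError(ValueError):
    """A column is constant across wards and cannot be normalized."""


def minmax_normalize(values, orientation=1):
    """Min-max normalize onto [0, 1], honouring indicator orientation.

    For a positively related indicator (orientation +1):
    K = (Z - Zmin) / (Zmax - Zmin); for a negatively related one, 1 - K.
    Accepts a Series (scalar orientation) or a DataFrame with a dict of
    per-column orientations.
    """
    if isinstance(values, pd.DataFrame):
        if not isinstance(orientation, dict):
            orientation = {c: orientation for c in values.columns}
        return pd.DataFrame(
            {c: minmax_normalize(values[c], orientation.get(c, 1)) for c in values.columns},
            index=values.index,
        )
    s = pd.Series(values, dtype=float)
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise DegenerateColumnError(
            f"column '{s.name}' is constant ({lo}); min-max normalization undefined"
        )
    k = (s - lo) / (hi - lo)
    return 1.0 - k if orientation < 0 else k


def _correlation(values) -> np.ndarray:
    df = pd.DataFrame(values)
    return df.corr().to_numpy()


def kmo(values) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over off-diagonal pairs,
    where q are the anti-image partial correlations obtained from the
    inverse correlation matrix. Returns NaN when both sums vanish (identity
    correlation matrix: the statistic is 0/0).
    """
    return kmo_from_correlation(_correlation(values))


def kmo_from_correlation(r) -> float:
    """KMO computed directly from a correlation matrix."""
    r = np.asarray(r, dtype=float)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular; KMO undefined") from e
    d = np.sqrt(np.diag(rinv))
    q = -rinv / np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    ssr = np.sum(r[off] ** 2)
    ssq = np.sum(q[off] ** 2)
    if ssr + ssq == 0:
        return float("nan")
    return float(ssr / (ssr + ssq))


def bartlett(values) -> tuple[float, int, float]:
    """Bartlett's test of sphericity: is the correlation matrix identity?

    chi2 = -(n - 1 - (2p + 5)/6) ln|R|, df = p(p-1)/2, with the p-value from
    the chi-squared distribution.
    """
    df_ = pd.DataFrame(values)
    n, p = df_.shape
    if n <= p:
        raise ValueError("Bartlett's test needs more observations than variables")
    r = _correlation(df_)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    dof = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, dof))
    return float(chi2), int(dof), pval


@dataclass
class PCAResult:
    """Everything the index construction derives from one indicator block."""

    correlation_matrix: pd.DataFrame
    eigenvalues: np.ndarray  # all p, descending
    loadings: pd.DataFrame  # indicators x retained components
    n_retained: int
    rotated_loadings: pd.DataFrame | None = None  # None when 1 component
    rotated_eigenvalues: np.ndarray | None = None
    factor_scores: pd.DataFrame | None = None
    weights: np.ndarray | None = None
    kmo: float = float("nan")
    bartlett_chi2: float = float("nan")
    bartlett_df: int = 0
    bartlett_p: float = float("nan")

    @property
    def variance_pct(self) -> np.ndarray:
        """Percent of total variance per (unrotated) eigenvalue."""
        return self.eigenvalues / len(self.eigenvalues) * 100.0

    def report(self) -> dict:
        """JSON-serializable summary (eigenvalues, loadings, tests, weights)."""
        rep = {
            "kmo": self.kmo,
            "bartlett": {
                "chi2": self.bartlett_chi2,
                "df": self.bartlett_df,
                "p": self.bartlett_p,
            },
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_pct": self.variance_pct.tolist(),
            "n_retained": self.n_retained,
            "loadings": self.loadings.round(6).to_dict(),
            "weights": None if self.weights is None else self.weights.tolist(),
        }
        if self.rotated_loadings is not None:
            rep["rotated_loadings"] = self.rotated_loadings.round(6).to_dict()
            rep["rotated_eigenvalues"] = self.rotated_eigenvalues.tolist()
        return rep


def _flip_signs(load: np.ndarray) -> np.ndarray:
    """Make each component's largest-magnitude loading positive."""
    out = load.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca(values, kaiser_threshold: float = 1.0, min_retain: int = 0) -> PCAResult:
    """Correlation-matrix PCA with Kaiser retention.

    ``values`` is a ward x indicator table (DataFrame or array). Loadings are
    eigenvectors scaled by sqrt(eigenvalue); components with eigenvalue
    strictly above ``kaiser_threshold`` are retained — possibly none (e.g. an
    identity correlation matrix, where every eigenvalue is exactly 1).
    ``min_retain`` forces a floor on the retained count for callers that need
    a component to exist.
    """
    df = pd.DataFrame(values)
    if (df.nunique() <= 1).any():
        bad = df.columns[df.nunique() <= 1].tolist()
        raise DegenerateColumnError(f"constant columns cannot be standardized: {bad}")
    r = _correlation(df)
    corr = pd.DataFrame(r, index=df.columns, columns=df.columns)
    evals, evecs = np.linalg.eigh(r)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # small eps so an eigenvalue of exactly 1 (identity correlation) is not
    # retained on floating-point noise alone
    n_ret = int(np.sum(evals > kaiser_threshold + 1e-9))
    if n_ret < min_retain:
        logger.warning(
            "only %d eigenvalues exceed %.2f (Kaiser); retaining %d",
            n_ret, kaiser_threshold, min_retain,
        )
        n_ret = min_retain
    load = evecs[:, :n_ret] * np.sqrt(np.clip(evals[:n_ret], 0, None))
    load = _flip_signs(load)
    loadings = pd.DataFrame(
        load, index=df.columns, columns=[f"PC{i + 1}" for i in range(n_ret)]
    )
    return PCAResult(
        correlation_matrix=corr,
        eigenvalues=evals,
        loadings=loadings,
        n_retained=n_ret,
    )


def varimax(
    loadings,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Varimax rotation of a loading matrix (>= 2 components).

    Orthogonal rotation maximizing the variance of squared loadings per
    component, with Kaiser row-normalization (rows scaled to unit communality
    during the search, rescaled afterwards), iterated until the criterion
    improves by less than ``tol``.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2 or L.shape[1] < 2:
        raise ValueError("varimax needs at least 2 components")
    p, m = L.shape
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        work = L / h[:, None]
    else:
        h = np.ones(p)
        work = L.copy()
    # Kaiser's pairwise planar rotations with the closed-form angle; sweeps
    # repeat until the criterion stops improving
    crit_old = varimax_criterion(work)
    for _ in range(max_iter):
        for j in range(m - 1):
            for k in range(j + 1, m):
                x, y = work[:, j].copy(), work[:, k].copy()
                u = x * x - y * y
                v = 2.0 * x * y
                num = 2.0 * (p * (u * v).sum() - u.sum() * v.sum())
                den = p * (u * u - v * v).sum() - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                work[:, j] = c * x + s * y
                work[:, k] = -s * x + c * y
        crit = varimax_criterion(work)
        if crit - crit_old <= tol:
            break
        crit_old = crit
    out = work * h[:, None]
    # order by explained variance, then fix signs for reproducibility
    ssq = (out**2).sum(axis=0)
    out = out[:, np.argsort(ssq)[::-1]]
    return _flip_signs(out)


def varimax_criterion(loadings) -> float:
    """The raw varimax objective: sum over components of var(lambda^2)."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def factor_scores(standardized, correlation, loadings) -> np.ndarray:
    """Regression-method component scores: Z R^-1 Lambda.

    ``standardized`` is the ward x indicator z-score matrix, ``correlation``
    the indicator correlation matrix and ``loadings`` the (rotated) loading
    matrix. Scores have zero mean per component by construction.
    """
    z = np.asarray(standardized, dtype=float)
    r = np.asarray(correlation, dtype=float)
    lam = np.asarray(loadings, dtype=float)
    if lam.ndim == 1:
        lam = lam[:, None]
    try:
        coef = np.linalg.solve(r, lam)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular correlation matrix; scores undefined") from e
    return z @ coef


def component_weights(rotated_eigenvalues) -> np.ndarray:
    """Variance-ratio weights W_j = lambda_j / sum(lambda)."""
    lam = np.asarray(rotated_eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("no eigenvalues given")
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    return lam / lam.sum()


def composite_index(scores, weights) -> np.ndarray:
    """Weighted component-score sum, min-max rescaled onto [0, 1].

    With a single component the lone score column is used directly before
    rescaling.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    combined = s @ w
    lo, hi = combined.min(), combined.max()
    if hi == lo:
        raise DegenerateColumnError("composite is constant across wards")
    return (combined - lo) / (hi - lo)


def classify(index_values, ddof: int = 1) -> pd.Series:
    """Five-level SD-bin labels (shared classification scheme)."""
    return sd_classify(index_values, ddof=ddof)


def build_composite_index(
    table: pd.DataFrame,
    orientation: dict[str, int] | None = None,
    name: str = "index",
) -> tuple[pd.DataFrame, PCAResult]:
    """Full index construction for one indicator block.

    Returns a per-ward DataFrame with columns ``value`` (the [0, 1] index)
    and ``category``, plus the :class:`PCAResult` audit trail. KMO below 0.5
    is logged as a warning, not an error.
    """
    orientation = orientation or {c: +1 for c in table.columns}
    normed = minmax_normalize(table, orientation)
    z = (normed - normed.mean()) / normed.std(ddof=1)

    res = pca(z, min_retain=1)
    res.kmo = kmo(z)
    res.bartlett_chi2, res.bartlett_df, res.bartlett_p = bartlett(z)
    if np.isnan(res.kmo) or res.kmo < KMO_ACCEPTABLE:
        logger.warning("KMO %.3f below the %.1f adequacy floor for %s",
                       res.kmo, KMO_ACCEPTABLE, name)

    if res.n_retained >= 2:
        rot = varimax(res.loadings.to_numpy())
        res.rotated_loadings = pd.DataFrame(
            rot, index=res.loadings.index, columns=res.loadings.columns
        )
        res.rotated_eigenvalues = (rot**2).sum(axis=0)
        lam = res.rotated_loadings
    else:
        res.rotated_eigenvalues = res.eigenvalues[: res.n_retained].copy()
        lam = res.loadings

    scores = factor_scores(z.to_numpy(), res.correlation_matrix.to_numpy(), lam.to_numpy())
    res.factor_scores = pd.DataFrame(scores, index=table.index, columns=lam.columns)
    res.weights = component_weights(res.rotated_eigenvalues)

    value = composite_index(scores, res.weights)
    out = pd.DataFrame({"value": value}, index=table.index)
    out["category"] = classify(out["value"])
    out.index.name = table.index.name or "ward_id"
    return out, res
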