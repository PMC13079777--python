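"""Shared test utilities: exact-correlation data construction and
loading-matrix alignment for recovery checks."""

import numpy as np


def exact_corr_data(rng, n, target_corr):
    """Data whose *sample* correlation matrix equals ``target_corr`` exactly.

    Centered random columns are orthonormalized (QR), which keeps them
    zero-mean, then recombined through the Cholesky factor of the target.
    """
    target = np.asarray(target_corr, dtype=float)
    p = target.shape[0]
    x = rng.standard_normal((n, p))
    x -= x.mean(axis=0)
    q, _ = np.linalg.qr(x)
    return q @ np.linalg.cholesky(target).T


def align_loadings(estimated, truth):
    """Permute and sign-flip estimated loading columns to best match truth."""
    est = np.asarray(estimated, dtype=float)
    tru = np.asarray(truth, dtype=float)
    m = tru.shape[1]
    used = set()
    cols, signs = [], []
    for j in range(m):
        scores = [
            (abs(est[:, k] @ tru[:, j]), k) for k in range(est.shape[1]) if k not in used
        ]
        _, best = max(scores)
        used.add(best)
        sign = np.sign(est[:, best] @ tru[:, j]) or 1.0
        cols.append(best)
        signs.append(sign)
    return est[:, cols] * np.asarray(signs)
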