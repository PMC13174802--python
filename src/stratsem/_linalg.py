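"""Half-vectorization bookkeeping and small matrix helpers.

The whole package shares one vech convention: columns of the lower
triangle, including the diagonal, traversed left to right.  For k = 3 the
order is (0,0), (1,0), (2,0), (1,1), (2,1), (2,2).  Sampling covariance
matrices, model residuals and Jacobians all live in this coordinate
system.
"""

from __future__ import annotations

import numpy as np


def vech_pairs(k: int) -> list[tuple[int, int]]:
    """(row, col) index pairs of vech order for a k x k symmetric matrix."""
    return [(i, j) for j in range(k) for i in range(j, k)]


def vech_position(i: int, j: int, k: int) -> int:
    """Position of element (i, j) (order-free) in the vech of a k x k matrix."""
    if i < j:
        i, j = j, i
    return j * k - j * (j - 1) // 2 + (i - j)


def vech(m: np.ndarray) -> np.ndarray:
    k = m.shape[0]
    rows, cols = zip(*vech_pairs(k))
    return np.asarray(m)[list(rows), list(cols)]


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    out = np.empty((k, k), dtype=float)
    for pos, (i, j) in enumerate(vech_pairs(k)):
        out[i, j] = v[pos]
        out[j, i] = v[pos]
    return out


def diag_positions(k: int) -> list[int]:
    """vech positions of the diagonal elements."""
    return [vech_position(i, i, k) for i in range(k)]


def offdiag_positions(k: int) -> list[int]:
    """vech positions of strictly-lower-triangle elements, vech order."""
    return [pos for pos, (i, j) in enumerate(vech_pairs(k)) if i > j]


def jackknife_cov(loo: np.ndarray) -> np.ndarray:
    """Delete-one-block jackknife covariance of a vector statistic.

    Parameters
    ----------
    loo : (b, p) array
        Leave-one-block-out re-estimates of the p-vector.

    Returns
    -------
    (p, p) covariance ``((b-1)/b) * sum_i (theta_i - mean)(theta_i - mean)'``,
    positive semidefinite by construction.
    """
    loo = np.atleast_2d(np.asarray(loo, dtype=float))
    b = loo.shape[0]
    centred = loo - loo.mean(axis=0)
    return (b - 1) / b * centred.T @ centred


def is_psd(m: np.ndarray, tol: float = 1e-8) -> bool:
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        return True
    w = np.linalg.eigvalsh((m + m.T) / 2.0)
    scale = max(1.0, float(np.max(np.abs(w))))
    return bool(w.min() >= -tol * scale)


def nearest_correlation(r: np.ndarray, tol: float = 1e-10, max_iter: int = 50) -> np.ndarray:
    """Project a symmetric matrix to the nearest unit-diagonal PSD matrix.

    Eigenvalue clipping alternated with diagonal rescaling; adequate for
    the mildly indefinite matrices produced by hand-filled presets.
    """
    x = (np.asarray(r, dtype=float) + np.asarray(r).T) / 2.0
    for _ in range(max_iter):
        w, u = np.linalg.eigh(x)
        if w.min() >= -tol:
            break
        x = (u * np.clip(w, 0.0, None)) @ u.T
        d = np.sqrt(np.clip(np.diag(x), 1e-12, None))
        x = x / np.outer(d, d)
        np.fill_diagonal(x, 1.0)
        x = (x + x.T) / 2.0
    np.fill_diagonal(x, 1.0)
    return x
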