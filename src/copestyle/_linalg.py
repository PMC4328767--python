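"""Small shared linear-algebra helpers for symmetric-matrix bookkeeping."""

from __future__ import annotations

import numpy as np


def vech_indices(k: int):
    """Row/column indices of the lower triangle in row-major order.

    Ordering is (0,0), (1,0), (1,1), (2,0), ... — the convention used
    everywhere a symmetric matrix is flattened in this package.
    """
    rows, cols = [], []
    for i in range(k):
        for j in range(i + 1):
            rows.append(i)
            cols.append(j)
    return np.asarray(rows), np.asarray(cols)


def vech(mat: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (lower triangle, row-major)."""
    k = mat.shape[0]
    r, c = vech_indices(k)
    return np.asarray(mat)[r, c]


def unvech(v: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`vech`: rebuild the full symmetric matrix."""
    v = np.asarray(v, dtype=float)
    if len(v) != k * (k + 1) // 2:
        raise ValueError(f"expected {k*(k+1)//2} elements for k={k}, got {len(v)}")
    out = np.zeros((k, k))
    r, c = vech_indices(k)
    out[r, c] = v
    out[c, r] = v
    return out


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    sym = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, eps, None)
    return (v * w) @ v.T
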