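"""Eigen structure of the among-individual matrix, with bootstrap HPDs.

A dominant first eigenvector of the among-individual covariance matrix
``I`` with same-sign loadings of similar magnitude is the signature of
a single latent axis of personality (shy-bold).  Point decomposition
is deterministic; uncertainty in the loadings comes from a parametric
bootstrap: the unique elements of ``I`` are redrawn from a multivariate
normal centered at the REML estimate with its sampling
variance-covariance matrix, each draw is eigen-decomposed, and the
loading distributions are summarized by 95% highest-posterior-density
intervals.

Bootstrap draws that are not positive definite are *not* rejected — a
symmetric eigen decomposition is always defined — but their frequency
is reported so users can judge how close the estimate sits to the PSD
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._linalg import unvech, vech

__all__ = ["EigenBootSummary", "bootstrap_loadings", "eigen_decompose",
           "hpd_interval"]


@dataclass
class EigenBootSummary:
    eigenvalues: np.ndarray          # descending
    variance_shares: np.ndarray      # percent of trace
    loadings: np.ndarray             # columns = eigenvectors, unit norm
    trait_names: Optional[list] = None
    hpd_lower: Optional[np.ndarray] = None   # per-trait EV1 loading, 95% HPD
    hpd_upper: Optional[np.ndarray] = None
    n_draws: int = 0
    seed: Optional[int] = None
    share_of_draws_nonPD: Optional[float] = None

    @property
    def ev1(self) -> np.ndarray:
        return self.loadings[:, 0]

    @property
    def ev1_share(self) -> float:
        return float(self.variance_shares[0])


def _stable_sign(vec: np.ndarray) -> np.ndarray:
    """Orient an eigenvector so its loading sum is positive (tie: first
    nonzero loading positive)."""
    s = vec.sum()
    if s != 0:
        return vec if s > 0 else -vec
    nz = np.flatnonzero(vec)
    if len(nz) and vec[nz[0]] < 0:
        return -vec
    return vec


def eigen_decompose(I_hat: np.ndarray, trait_names=None,
                    sym_tol: float = 1e-8) -> EigenBootSummary:
    """Sorted eigen decomposition with sign-stabilized loadings.

    Variance shares are eigenvalue / trace x 100; for a PSD input they
    sum to 100%.  The input is symmetrized; asymmetry beyond
    ``sym_tol`` is an error.
    """
    M = np.asarray(I_hat, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(M - M.T)) > sym_tol:
        raise ValueError(f"matrix asymmetric beyond tolerance {sym_tol}")
    M = 0.5 * (M + M.T)
    w, v = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    for j in range(v.shape[1]):
        v[:, j] = _stable_sign(v[:, j])
    tr = np.trace(M)
    shares = 100.0 * w / tr if tr != 0 else np.full_like(w, np.nan)
    return EigenBootSummary(eigenvalues=w, variance_shares=shares,
                            loadings=v, trait_names=list(trait_names)
                            if trait_names is not None else None)


def hpd_interval(samples, mass: float = 0.95):
    """Shortest contiguous window over the sorted samples holding
    ``ceil(mass * n)`` points; ties broken by the leftmost window."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))       # argmin returns the first minimum
    return float(x[i]), float(x[i + m - 1])


def bootstrap_loadings(I_hat: np.ndarray, S_hat: np.ndarray,
                       n_draws: int = 5000, seed: Optional[int] = None,
                       mass: float = 0.95,
                       trait_names=None) -> EigenBootSummary:
    """Parametric bootstrap on the first-eigenvector loadings.

    Draws the ``k(k+1)/2`` unique elements of ``I`` jointly from
    ``MVN(vech(I_hat), S_hat)``, rebuilds each symmetric matrix,
    decomposes it, aligns each draw's first eigenvector to the point
    estimate's (sign flip if their dot product is negative), and
    returns per-trait HPD intervals of the EV1 loadings.
    Deterministic given ``seed``.
    """
    point = eigen_decompose(I_hat, trait_names=trait_names)
    k = point.loadings.shape[0]
    mu = vech(0.5 * (np.asarray(I_hat, float) + np.asarray(I_hat, float).T))
    S = np.asarray(S_hat, dtype=float)
    if S.shape != (len(mu), len(mu)):
        raise ValueError(
            f"S_hat must be {len(mu)} x {len(mu)} for {k} traits")
    rng = np.random.default_rng(seed)
    S = 0.5 * (S + S.T)
    draws = rng.multivariate_normal(mu, S, size=n_draws, method="eigh",
                                    check_valid="ignore")
    ev1_draws = np.empty((n_draws, k))
    n_nonpd = 0
    ref = point.ev1
    for i in range(n_draws):
        M = unvech(draws[i], k)
        w, v = np.linalg.eigh(M)
        if w[0] < 0:
            n_nonpd += 1
        vec = v[:, -1]
        if vec @ ref < 0:
            vec = -vec
        ev1_draws[i] = vec
    lo = np.empty(k)
    hi = np.empty(k)
    for t in range(k):
        lo[t], hi[t] = hpd_interval(ev1_draws[:, t], mass)
    return EigenBootSummary(
        eigenvalues=point.eigenvalues, variance_shares=point.variance_shares,
        loadings=point.loadings, trait_names=point.trait_names,
        hpd_lower=lo, hpd_upper=hi, n_draws=n_draws, seed=seed,
        share_of_draws_nonPD=n_nonpd / n_draws)
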