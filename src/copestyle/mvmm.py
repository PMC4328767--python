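"""Multivariate mixed model with an individual-identity random effect.

The model for trait *t* of individual *i* in trial *j* is

    y_ijt = x_ijt' beta_t + u_it + e_ijt

with trait-vector random effects u_i ~ MVN(0, I) shared across an
individual's trials and residuals e_ij ~ MVN(0, R) shared within a
trial record.  ``I`` (among-individual) and ``R`` (within-individual)
can each be structured:

* ``absent``       — no individual effect (I only),
* ``diagonal``     — variances free, covariances fixed at zero,
* ``unstructured`` — variances and covariances free, kept PSD through
  a log-Cholesky factor,
* ``unstructured_free`` (I only) — symmetric but otherwise
  unconstrained, the convention of classical REML software for fully
  unstructured among-individual matrices; the estimate may be
  indefinite, which avoids boundary-truncation bias when the true
  matrix is nearly singular.

Estimation is by restricted maximum likelihood (REML).  Covariance
matrices are parameterized through a log-Cholesky factor so every
iterate is valid; fixed effects are profiled out by generalized least
squares; the optimizer is quasi-Newton (L-BFGS-B) with analytic
gradients and a small set of fixed multi-start initializations so the
optimum is reproducible.  Likelihood evaluation groups individuals by
their missing-data pattern, which makes the balanced 20 x 5 design
essentially a two-pattern problem.

:func:`reml_loglik_oracle` re-evaluates the REML log-likelihood by
building the full stacked covariance matrix of every observation pair
directly — an independent (slow, O(N^3)) route used to cross-check the
fast block-wise evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize

from ._linalg import vech, vech_indices
from .data_model import DataError, ObservationTable, TraitSpec

__all__ = [
    "CovarianceFit",
    "Design",
    "ModelSpec",
    "build_design",
    "reml_fit",
    "reml_loglik_at",
    "reml_loglik_oracle",
]

_STRUCTS_I = ("absent", "diagonal", "unstructured", "unstructured_free")
_STRUCTS_R = ("diagonal", "unstructured")

#: variance below which an among-individual component is reported as a
#: boundary (zero) estimate
_BOUNDARY_VAR = 1e-6
_LOG_SD_BOUNDS = (-9.0, 9.0)
_OFFDIAG_BOUNDS = (-40.0, 40.0)


@dataclass(frozen=True)
class ModelSpec:
    """Traits plus the structural form of the I and R matrices.

    The four-model hierarchy used for inference is:

    1. ``I='absent'``, ``R='diagonal'`` — no individual effect, no
       trait covariance;
    2. ``I='diagonal'``, ``R='diagonal'`` — repeatable variance, no
       covariance;
    3. ``I='diagonal'``, ``R='unstructured'`` — within-individual
       covariance added;
    4. ``I='unstructured'``, ``R='unstructured'`` — among-individual
       covariance added.
    """

    traits: tuple
    I_structure: str = "unstructured"
    R_structure: str = "unstructured"
    trial_as_factor: bool = True

    def __post_init__(self):
        if self.I_structure not in _STRUCTS_I:
            raise ValueError(f"I_structure must be one of {_STRUCTS_I}")
        if self.R_structure not in _STRUCTS_R:
            raise ValueError(f"R_structure must be one of {_STRUCTS_R}")
        object.__setattr__(self, "traits", tuple(self.traits))

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self):
        return [t.name for t in self.traits]

    def n_cov_params(self) -> int:
        k = self.k
        n = 0
        if self.I_structure == "diagonal":
            n += k
        elif self.I_structure in ("unstructured", "unstructured_free"):
            n += k * (k + 1) // 2
        n += k if self.R_structure == "diagonal" else k * (k + 1) // 2
        return n


# ---------------------------------------------------------------------------
# Design construction


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    col_names: list
    ind_codes: np.ndarray
    rec_codes: np.ndarray
    trait_codes: np.ndarray
    trait_names: list
    ind_ids: list

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _trait_design_columns(df: pd.DataFrame, spec: TraitSpec,
                          trial_as_factor: bool):
    """Fixed-effect columns for one trait on its included rows."""
    cols, names = [], []
    n = len(df)
    for eff in spec.fixed_effects:
        if eff == "mean":
            cols.append(np.ones(n))
            names.append(f"{spec.name}:mean")
        elif eff == "trial_number":
            levels = sorted(df["trial_number"].unique())
            if len(levels) < 2:
                raise DataError(
                    f"trial_number has a single level for trait {spec.name}")
            if trial_as_factor:
                for lv in levels[1:]:
                    cols.append((df["trial_number"] == lv).to_numpy(float))
                    names.append(f"{spec.name}:trial[{lv}]")
            else:
                x = df["trial_number"].to_numpy(float)
                cols.append(x - x.mean())
                names.append(f"{spec.name}:trial_linear")
        elif eff == "stack":
            levels = sorted(df["stack"].astype(str).unique())
            if len(levels) < 2:
                raise DataError(
                    f"stack has a single level for trait {spec.name}")
            for lv in levels[1:]:
                cols.append((df["stack"].astype(str) == lv).to_numpy(float))
                names.append(f"{spec.name}:stack[{lv}]")
        elif eff in ("day_order", "mass"):
            x = df[eff].to_numpy(float)
            cols.append(x - np.nanmean(x))
            names.append(f"{spec.name}:{eff}")
        else:  # pragma: no cover - validated by TraitSpec
            raise ValueError(eff)
    return np.column_stack(cols), names


def build_design(table: ObservationTable, spec: ModelSpec) -> Design:
    """Stack responses trait-within-record and build fixed-effect design.

    Rows missing a trait value (or any covariate that trait uses) are
    dropped trait-wise, so traits may have different record counts.
    Covariates ``day_order`` and ``mass`` are mean-centered over each
    trait's included rows.  ``trial_number`` enters as a categorical
    factor by default.
    """
    from .data_model import prepare_trait

    df = table.data
    ind_ids = sorted(df["individual_id"].unique().tolist())
    ind_map = {v: i for i, v in enumerate(ind_ids)}
    rec_key = df["individual_id"].astype(str) + "\x00" + df["trial_number"].astype(str)
    rec_map = {v: i for i, v in enumerate(rec_key.unique())}

    per_trait = []
    total_p = 0
    for t_idx, tspec in enumerate(spec.traits):
        prepared = prepare_trait(df, tspec)
        needed = [c for c in tspec.fixed_effects if c not in ("mean",)]
        cov_cols = [c if c != "trial_number" else "trial_number" for c in needed]
        mask = prepared.notna()
        for c in cov_cols:
            if c not in df.columns:
                raise DataError(f"covariate column {c!r} missing from table")
            mask &= df[c].notna()
        sub = df[mask]
        if sub["individual_id"].nunique() < 2 or len(sub) < 2:
            raise DataError(
                f"trait {tspec.name} needs >= 2 observations on >= 2 individuals")
        Xt, names = _trait_design_columns(sub, tspec, spec.trial_as_factor)
        per_trait.append({
            "trait_idx": t_idx,
            "y": prepared[mask].to_numpy(float),
            "X": Xt,
            "names": names,
            "ind": df.loc[mask, "individual_id"].map(ind_map).to_numpy(int),
            "rec": rec_key[mask].map(rec_map).to_numpy(int),
        })
        total_p += Xt.shape[1]

    # assemble block-diagonal fixed-effect design
    rows = sum(len(d["y"]) for d in per_trait)
    y = np.empty(rows)
    X = np.zeros((rows, total_p))
    ind_codes = np.empty(rows, dtype=int)
    rec_codes = np.empty(rows, dtype=int)
    trait_codes = np.empty(rows, dtype=int)
    col_names = []
    r0, c0 = 0, 0
    for d in per_trait:
        n_t, p_t = d["X"].shape
        y[r0:r0 + n_t] = d["y"]
        X[r0:r0 + n_t, c0:c0 + p_t] = d["X"]
        ind_codes[r0:r0 + n_t] = d["ind"]
        rec_codes[r0:r0 + n_t] = d["rec"]
        trait_codes[r0:r0 + n_t] = d["trait_idx"]
        col_names.extend(d["names"])
        r0 += n_t
        c0 += p_t

    # sort observations individual-major, then record, then trait
    order = np.lexsort((trait_codes, rec_codes, ind_codes))
    y, X = y[order], X[order]
    ind_codes, rec_codes, trait_codes = (
        ind_codes[order], rec_codes[order], trait_codes[order])

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("fixed-effect design is rank deficient")

    return Design(y=y, X=X, col_names=col_names, ind_codes=ind_codes,
                  rec_codes=rec_codes, trait_codes=trait_codes,
                  trait_names=list(spec.trait_names), ind_ids=ind_ids)


# ---------------------------------------------------------------------------
# Covariance parameterizations


class _CovParam:
    """Map between an unconstrained vector and one covariance matrix."""

    def __init__(self, k: int, structure: str):
        self.k = k
        self.structure = structure
        if structure == "absent":
            self.n_par = 0
        elif structure == "diagonal":
            self.n_par = k
        else:
            self.n_par = k * (k + 1) // 2
        self._vr, self._vc = vech_indices(k)

    def matrix(self, theta: np.ndarray) -> np.ndarray:
        k = self.k
        if self.structure == "absent":
            return np.zeros((k, k))
        if self.structure == "diagonal":
            return np.diag(np.exp(2.0 * theta))
        if self.structure == "unstructured_free":
            M = np.zeros((k, k))
            M[self._vr, self._vc] = theta
            M[self._vc, self._vr] = theta
            return M
        L = np.zeros((k, k))
        L[self._vr, self._vc] = theta
        d = np.exp(np.diag(L).copy())
        L[np.diag_indices(k)] = d
        return L @ L.T

    def derivatives(self, theta: np.ndarray):
        """List of dM/dtheta_m matrices at ``theta``."""
        k = self.k
        if self.structure == "absent":
            return []
        if self.structure == "diagonal":
            out = []
            for t in range(k):
                D = np.zeros((k, k))
                D[t, t] = 2.0 * np.exp(2.0 * theta[t])
                out.append(D)
            return out
        if self.structure == "unstructured_free":
            out = []
            for i, j in zip(self._vr, self._vc):
                D = np.zeros((k, k))
                D[i, j] = D[j, i] = 1.0
                out.append(D)
            return out
        L = np.zeros((k, k))
        L[self._vr, self._vc] = theta
        d = np.exp(np.diag(L).copy())
        L[np.diag_indices(k)] = d
        out = []
        for m, (i, j) in enumerate(zip(self._vr, self._vc)):
            dL = np.zeros((k, k))
            dL[i, j] = d[i] if i == j else 1.0
            out.append(dL @ L.T + L @ dL.T)
        return out

    def theta_from_matrix(self, M: np.ndarray) -> np.ndarray:
        if self.structure == "absent":
            return np.zeros(0)
        if self.structure == "diagonal":
            return 0.5 * np.log(np.clip(np.diag(M), 1e-12, None))
        if self.structure == "unstructured_free":
            return np.asarray(M, float)[self._vr, self._vc].copy()
        L = np.linalg.cholesky(M + 1e-10 * np.eye(self.k))
        theta = L[self._vr, self._vc].copy()
        diag_pos = np.cumsum(np.arange(1, self.k + 1)) - 1
        theta[diag_pos] = np.log(np.clip(np.diag(L), 1e-9, None))
        return theta

    def bounds(self):
        if self.structure == "absent":
            return []
        if self.structure == "diagonal":
            return [_LOG_SD_BOUNDS] * self.k
        if self.structure == "unstructured_free":
            return [_OFFDIAG_BOUNDS] * self.n_par
        out = []
        for i, j in zip(self._vr, self._vc):
            out.append(_LOG_SD_BOUNDS if i == j else _OFFDIAG_BOUNDS)
        return out


# ---------------------------------------------------------------------------
# REML likelihood (block-wise, pattern-grouped)


class _REMLProblem:
    def __init__(self, design: Design, spec: ModelSpec):
        self.design = design
        self.spec = spec
        self.k = spec.k
        self.pI = _CovParam(self.k, spec.I_structure)
        self.pR = _CovParam(self.k, spec.R_structure)
        self.n_par = self.pI.n_par + self.pR.n_par
        self._group_patterns()

    def _group_patterns(self):
        d = self.design
        starts = np.flatnonzero(np.diff(d.ind_codes, prepend=-1))
        ends = np.append(starts[1:], len(d.ind_codes))
        patterns = {}
        for s, e in zip(starts, ends):
            recs = d.rec_codes[s:e]
            # local record rank within individual
            _, local = np.unique(recs, return_inverse=True)
            key = tuple(zip(local.tolist(), d.trait_codes[s:e].tolist()))
            patterns.setdefault(key, []).append((s, e))
        self.patterns = []
        k = self.k
        for key, members in patterns.items():
            local = np.array([a for a, _ in key])
            tr = np.array([b for _, b in key])
            same_rec = local[:, None] == local[None, :]
            # stack members: responses in the last column
            XB = np.stack([
                np.column_stack([d.X[s:e], d.y[s:e]]) for s, e in members])
            n_i = len(tr)
            n_rec = int(local.max()) + 1
            # selection matrices collapsing observation rows to traits
            # (S_I) and to record x trait cells (S_R); the gradient uses
            # them to reduce block derivatives to k x k contractions
            S_I = np.zeros((k, n_i))
            S_I[tr, np.arange(n_i)] = 1.0
            S_R = np.zeros((n_rec, k, n_i))
            S_R[local, tr, np.arange(n_i)] = 1.0
            self.patterns.append({
                "traits": tr, "same_rec": same_rec, "XB": XB,
                "S_I": S_I, "S_R": S_R})

    def split(self, theta):
        return theta[: self.pI.n_par], theta[self.pI.n_par:]

    def matrices(self, theta):
        tI, tR = self.split(theta)
        return self.pI.matrix(tI), self.pR.matrix(tR)

    def theta_init(self, frac_I: float):
        d = self.design
        v = np.array([np.var(d.y[d.trait_codes == t], ddof=1)
                      if np.sum(d.trait_codes == t) > 1 else 1.0
                      for t in range(self.k)])
        v = np.clip(v, 1e-6, None)
        tI = self.pI.theta_from_matrix(np.diag(np.clip(frac_I * v, 1e-8, None)))
        tR = self.pR.theta_from_matrix(np.diag((1.0 - frac_I) * v))
        return np.concatenate([tI, tR])

    def bounds(self):
        return self.pI.bounds() + self.pR.bounds()

    # -- likelihood and gradient ------------------------------------------

    def _accumulate(self, I_mat, R_mat):
        """One pass over patterns: GLS pieces plus per-pattern solves."""
        d = self.design
        p = d.p
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        logdet = 0.0
        cache = []
        for pat in self.patterns:
            tr = pat["traits"]
            V = I_mat[np.ix_(tr, tr)].copy()
            Rsub = R_mat[np.ix_(tr, tr)]
            V[pat["same_rec"]] += Rsub[pat["same_rec"]]
            cfac = sla.cho_factor(V, lower=True)
            XB = pat["XB"]                      # (members, n_i, p + 1)
            mem, n_i, _ = XB.shape
            logdet += 2.0 * np.sum(np.log(np.diag(cfac[0]))) * mem
            W = sla.cho_solve(cfac, XB.transpose(1, 0, 2).reshape(n_i, -1))
            W = W.reshape(n_i, mem, p + 1).transpose(1, 0, 2)
            A, w = W[:, :, :p], W[:, :, p]      # V^{-1}X, V^{-1}y per member
            Xs, ys = XB[:, :, :p], XB[:, :, p]
            XtVX += np.tensordot(Xs, A, axes=([0, 1], [0, 1]))
            XtVy += np.einsum("mnp,mn->p", Xs, w)
            ytVy += float(np.sum(ys * w))
            cache.append((pat, cfac, A, w))
        return XtVX, XtVy, ytVy, logdet, cache

    def loglik(self, theta, grad: bool = False):
        d = self.design
        I_mat, R_mat = self.matrices(theta)
        try:
            XtVX, XtVy, ytVy, logdet, cache = self._accumulate(I_mat, R_mat)
            cG = sla.cho_factor(XtVX)
        except (np.linalg.LinAlgError, ValueError):
            return (-1e12, np.zeros(self.n_par)) if grad else -1e12
        beta = sla.cho_solve(cG, XtVy)
        ld_XtVX = 2.0 * np.sum(np.log(np.diag(cG[0])))
        yPy = ytVy - XtVy @ beta
        n, pp = d.n_obs, d.p
        ll = -0.5 * ((n - pp) * np.log(2.0 * np.pi) + logdet + ld_XtVX + yPy)
        if not grad:
            return ll

        # analytic gradient: for each covariance parameter m with
        # block derivative D,
        #   dl/dm = -1/2 [ tr(V^-1 D) - tr(G X'V^-1 D V^-1 X) - q'Dq ]
        # accumulated per missing-data pattern, q = V^-1 (y - X beta).
        tI, tR = self.split(theta)
        dIs = self.pI.derivatives(tI)
        dRs = self.pR.derivatives(tR)
        n_par = self.n_par
        nI = self.pI.n_par
        term1 = np.zeros(n_par)
        term3 = np.zeros(n_par)
        M2 = np.zeros((n_par, pp, pp))
        k = self.k
        dI_stack = np.stack(dIs) if dIs else None    # (nI, k, k)
        dR_stack = np.stack(dRs) if dRs else None
        for pat, cfac, A, w in cache:
            mem, n_i, _ = A.shape
            p1 = pp + 1
            Vinv = sla.cho_solve(cfac, np.eye(n_i))
            q = w - A @ beta                    # (members, n_i)
            Aq = np.concatenate([A, q[:, :, None]], axis=2)
            if dI_stack is not None:
                S_I = pat["S_I"]
                C = np.matmul(S_I, Aq).reshape(mem, k * p1)
                T = np.tensordot(C, C, axes=(0, 0)).reshape(k, p1, k, p1)
                T = T.transpose(0, 2, 1, 3)     # (k, k, p+1, p+1)
                Vc = S_I @ Vinv @ S_I.T
                term1[:nI] += mem * np.tensordot(dI_stack, Vc, axes=2)
                term3[:nI] += np.tensordot(dI_stack, T[:, :, pp, pp], axes=2)
                M2[:nI] += np.tensordot(dI_stack,
                                        np.ascontiguousarray(T[:, :, :pp, :pp]),
                                        axes=2)
            if dR_stack is not None:
                S_R = pat["S_R"]
                r = S_R.shape[0]
                S_Rf = S_R.reshape(r * k, n_i)
                Cr = np.matmul(S_Rf, Aq).reshape(mem * r, k * p1)
                Tr = np.tensordot(Cr, Cr, axes=(0, 0)).reshape(k, p1, k, p1)
                Tr = Tr.transpose(0, 2, 1, 3)
                VS = S_Rf @ Vinv @ S_Rf.T       # (r*k, r*k)
                Vcr = np.einsum("rkrl->kl",
                                VS.reshape(r, k, r, k))
                term1[nI:] += mem * np.tensordot(dR_stack, Vcr, axes=2)
                term3[nI:] += np.tensordot(dR_stack, Tr[:, :, pp, pp], axes=2)
                M2[nI:] += np.tensordot(dR_stack,
                                        np.ascontiguousarray(Tr[:, :, :pp, :pp]),
                                        axes=2)
        G = sla.cho_solve(cG, np.eye(pp))
        term2 = np.tensordot(M2, G, axes=([1, 2], [0, 1]))
        grad_vec = -0.5 * (term1 - term2 - term3)
        return ll, grad_vec

    def gls(self, theta):
        """Fixed-effect estimates and their covariance at ``theta``."""
        I_mat, R_mat = self.matrices(theta)
        XtVX, XtVy, _, _, _ = self._accumulate(I_mat, R_mat)
        cov = np.linalg.inv(XtVX)
        beta = cov @ XtVy
        return beta, cov


# ---------------------------------------------------------------------------
# Fit result


@dataclass
class CovarianceFit:
    """Converged REML solution for one :class:`ModelSpec`."""

    spec: ModelSpec
    trait_names: list
    beta: pd.DataFrame
    I_hat: np.ndarray
    R_hat: np.ndarray
    reml_loglik: float
    n_cov_params: int
    n_obs: int
    converged: bool
    boundary: bool
    boundary_traits: list
    theta: np.ndarray = field(repr=False, default=None)
    S_hat: Optional[np.ndarray] = field(repr=False, default=None)
    message: str = ""
    _problem: object = field(repr=False, default=None, compare=False)

    def V_I(self, trait: str) -> float:
        return float(self.I_hat[self._ti(trait), self._ti(trait)])

    def V_R(self, trait: str) -> float:
        return float(self.R_hat[self._ti(trait), self._ti(trait)])

    def _ti(self, trait: str) -> int:
        return self.trait_names.index(trait)

    def sampling_cov(self, which: str = "I") -> np.ndarray:
        """Sampling variance-covariance of estimated covariance elements.

        Computed from the inverse of the observed information of the
        REML log-likelihood at the optimum (Hessian by central
        differences of the analytic gradient), mapped to the
        covariance-element scale by the delta method.  ``which`` is
        ``"I"``, ``"R"`` or ``"both"`` (I elements first).
        """
        prob: _REMLProblem = self._problem
        theta = self.theta
        n_par = prob.n_par
        H = np.zeros((n_par, n_par))
        h = 1e-5 * np.maximum(1.0, np.abs(theta))
        for m in range(n_par):
            tp = theta.copy(); tp[m] += h[m]
            tm = theta.copy(); tm[m] -= h[m]
            _, gp = prob.loglik(tp, grad=True)
            _, gm = prob.loglik(tm, grad=True)
            H[m] = (gp - gm) / (2.0 * h[m])
        H = 0.5 * (H + H.T)
        info = -H
        S_theta = np.linalg.pinv(info, hermitian=True)

        tI, tR = prob.split(theta)
        dIs = prob.pI.derivatives(tI)
        dRs = prob.pR.derivatives(tR)
        k = prob.k
        nv = k * (k + 1) // 2
        cols = []
        if which in ("I", "both"):
            J_I = np.zeros((nv, n_par))
            for m, dM in enumerate(dIs):
                J_I[:, m] = vech(dM)
            cols.append(J_I)
        if which in ("R", "both"):
            J_R = np.zeros((nv, n_par))
            for m, dM in enumerate(dRs):
                J_R[:, prob.pI.n_par + m] = vech(dM)
            cols.append(J_R)
        J = np.vstack(cols)
        S = J @ S_theta @ J.T
        return 0.5 * (S + S.T)


# ---------------------------------------------------------------------------
# Fitting


_DEFAULT_STARTS = (0.3, 0.05, 0.6)


def reml_fit(table: ObservationTable, spec: ModelSpec,
             starts: Sequence[float] = _DEFAULT_STARTS,
             compute_S: bool = False, maxiter: int = 1000,
             ftol: float = 1e-12, gtol: float = 1e-8) -> CovarianceFit:
    """Fit the mixed model by REML.

    ``starts`` are among-individual variance fractions used as fixed
    preset initializations; the best converged optimum is returned, so
    the fit is deterministic given data and spec.  Among-individual
    variances that collapse to the parameter-space boundary are
    reported as exact zeros with ``boundary=True`` (the downstream
    likelihood-ratio tests use a chi-square mixture for this reason).
    """
    design = build_design(table, spec)
    prob = _REMLProblem(design, spec)

    def neg(theta):
        ll, g = prob.loglik(theta, grad=True)
        return -ll, -g

    if spec.I_structure == "unstructured_free":
        # The unconstrained surface has a hard infeasibility cliff
        # (stacked covariance not PD), so optimize in two stages: find
        # the PSD optimum under the log-Cholesky parameterization, then
        # refine from there without the PSD constraint.
        psd_spec = ModelSpec(spec.traits, "unstructured", spec.R_structure,
                             spec.trial_as_factor)
        psd_fit = reml_fit(table, psd_spec, starts=starts, maxiter=maxiter,
                           ftol=max(ftol, 1e-10), gtol=max(gtol, 1e-6))
        x0 = np.concatenate([
            vech(psd_fit.I_hat),
            prob.pR.theta_from_matrix(psd_fit.R_hat)])
        res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                       bounds=prob.bounds(),
                       options={"maxiter": maxiter, "ftol": max(ftol, 2e-10),
                                "gtol": max(gtol, 1e-6)})
        if -res.fun < psd_fit.reml_loglik:    # refinement cannot be worse
            res.x = np.concatenate([
                vech(psd_fit.I_hat),
                prob.pR.theta_from_matrix(psd_fit.R_hat)])
            res.fun = -psd_fit.reml_loglik
        best = (-res.fun, res)
    else:
        best = None
        for frac in starts:
            x0 = prob.theta_init(frac)
            res = minimize(neg, x0, jac=True, method="L-BFGS-B",
                           bounds=prob.bounds(),
                           options={"maxiter": maxiter, "ftol": ftol,
                                    "gtol": gtol})
            if best is None or -res.fun > best[0]:
                best = (-res.fun, res)
    ll, res = best
    theta = res.x
    I_hat, R_hat = prob.matrices(theta)

    boundary_traits = []
    if spec.I_structure in ("diagonal", "unstructured"):
        # PSD parameterizations can collapse a variance onto the
        # boundary of the parameter space; report those as exact zeros
        for t in range(spec.k):
            if I_hat[t, t] < _BOUNDARY_VAR:
                boundary_traits.append(spec.trait_names[t])
                I_hat[t, :] = 0.0
                I_hat[:, t] = 0.0
    boundary = bool(boundary_traits)

    beta_hat, beta_cov = prob.gls(theta)
    beta = pd.DataFrame({
        "effect": design.col_names,
        "estimate": beta_hat,
        "se": np.sqrt(np.clip(np.diag(beta_cov), 0.0, None)),
    })

    fit = CovarianceFit(
        spec=spec, trait_names=list(spec.trait_names), beta=beta,
        I_hat=I_hat, R_hat=R_hat, reml_loglik=float(ll),
        n_cov_params=prob.n_par, n_obs=design.n_obs,
        converged=bool(res.success), boundary=boundary,
        boundary_traits=boundary_traits, theta=theta,
        message=str(res.message), _problem=prob)
    if compute_S:
        fit.S_hat = fit.sampling_cov("I")
    return fit


def reml_loglik_at(table: ObservationTable, spec: ModelSpec,
                   I_mat: np.ndarray, R_mat: np.ndarray) -> float:
    """Block-wise REML log-likelihood at fixed (I, R), beta profiled."""
    design = build_design(table, spec)
    prob = _REMLProblem(design, spec)
    XtVX, XtVy, ytVy, logdet, _ = prob._accumulate(
        np.asarray(I_mat, float), np.asarray(R_mat, float))
    cG = sla.cho_factor(XtVX)
    beta = sla.cho_solve(cG, XtVy)
    yPy = ytVy - XtVy @ beta
    ld_XtVX = 2.0 * np.sum(np.log(np.diag(cG[0])))
    return float(-0.5 * ((design.n_obs - design.p) * np.log(2 * np.pi)
                         + logdet + ld_XtVX + yPy))


def reml_loglik_oracle(table: ObservationTable, spec: ModelSpec,
                       I_mat: np.ndarray, R_mat: np.ndarray,
                       max_obs: int = 200) -> float:
    """Brute-force REML log-likelihood via the full stacked covariance.

    Builds the N x N covariance of every observation pair directly —
    ``Cov(y_a, y_b) = [same individual] I[t_a, t_b] + [same record]
    R[t_a, t_b]`` — and evaluates the standard REML expression with
    dense determinants.  No optimization, no block shortcuts; intended
    as a test oracle on small instances.
    """
    design = build_design(table, spec)
    N = design.n_obs
    if N > max_obs:
        raise ValueError(f"oracle restricted to <= {max_obs} observations")
    I_mat = np.asarray(I_mat, float)
    R_mat = np.asarray(R_mat, float)
    V = np.zeros((N, N))
    for a in range(N):
        for b in range(N):
            va = 0.0
            if design.ind_codes[a] == design.ind_codes[b]:
                va += I_mat[design.trait_codes[a], design.trait_codes[b]]
                if design.rec_codes[a] == design.rec_codes[b]:
                    va += R_mat[design.trait_codes[a], design.trait_codes[b]]
            V[a, b] = va
    sign, ld_V = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("stacked covariance not positive definite")
    Vinv = np.linalg.inv(V)
    X, y = design.X, design.y
    XtVX = X.T @ Vinv @ X
    sign2, ld_XtVX = np.linalg.slogdet(XtVX)
    if sign2 <= 0:
        raise np.linalg.LinAlgError("X'V^{-1}X not positive definite")
    beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
    r = y - X @ beta
    yPy = r @ Vinv @ r
    p = X.shape[1]
    return float(-0.5 * ((N - p) * np.log(2 * np.pi) + ld_V + ld_XtVX + yPy))
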