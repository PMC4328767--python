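"""Model comparison, repeatability, and correlation inference.

Likelihood-ratio tests of variance components sit on the boundary of
the parameter space (a variance cannot be negative), so the asymptotic
null of a single-variance test is the 50:50 mixture
``0.5 chi2_{df-1} + 0.5 chi2_df`` (with ``chi2_0`` a point mass at
zero).  Multivariate model comparisons conservatively use the plain
chi-square with df equal to the number of added covariance parameters.

The four-model hierarchy (see :class:`copestyle.mvmm.ModelSpec`) tests,
in order: any among-individual variance (1 vs 2), any within-individual
trait covariance (2 vs 3), and an among-individual contribution to that
covariance (3 vs 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, ObservationTable, TraitSpec
from .mvmm import CovarianceFit, ModelSpec, reml_fit

__all__ = [
    "HierarchyResult",
    "LRTResult",
    "between_trial_correlations",
    "compare_hierarchy",
    "corr_from_cov",
    "lrt_pvalue",
    "paired_mean_change",
    "repeatability",
    "validation_correlation",
]

_CLAMP = 1e-6


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    mixture: str          # 'none' or 'half_chisq'
    p_value: float


def _chisq_sf(q: float, df: int) -> float:
    if df == 0:
        return 1.0 if q <= 0 else 0.0
    return float(stats.chi2.sf(q, df))


def lrt_pvalue(statistic: float, df: int, mixture: str = "none") -> LRTResult:
    """Upper-tail p-value for a (possibly boundary) likelihood-ratio test.

    ``mixture='half_chisq'`` applies the 50:50 ``chi2_{df-1}/chi2_df``
    mixture appropriate when a single variance is tested on its
    boundary.  Small negative statistics (|q| <= 1e-6) are clamped to
    zero as numerical noise.
    """
    if statistic < -_CLAMP:
        raise ValueError(f"negative LRT statistic {statistic}")
    if df < 1:
        raise ValueError("df must be >= 1")
    if mixture not in ("none", "half_chisq"):
        raise ValueError(f"unknown mixture {mixture!r}")
    q = max(0.0, float(statistic))
    if q == 0.0:
        p = 1.0
    elif mixture == "none":
        p = _chisq_sf(q, df)
    else:
        p = 0.5 * _chisq_sf(q, df - 1) + 0.5 * _chisq_sf(q, df)
    return LRTResult(statistic=q, df=df, mixture=mixture, p_value=min(p, 1.0))


@dataclass
class HierarchyResult:
    fits: dict                 # model number -> CovarianceFit
    tests: pd.DataFrame        # comparison, statistic, df, mixture, p_value

    def fit(self, model: int) -> CovarianceFit:
        return self.fits[model]


def _model_specs(traits, trial_as_factor=True):
    traits = tuple(traits)
    k = len(traits)
    specs = {
        1: ModelSpec(traits, "absent", "diagonal", trial_as_factor),
        2: ModelSpec(traits, "diagonal", "diagonal", trial_as_factor),
    }
    if k >= 2:
        specs[3] = ModelSpec(traits, "diagonal", "unstructured", trial_as_factor)
        specs[4] = ModelSpec(traits, "unstructured", "unstructured", trial_as_factor)
    return specs


def compare_hierarchy(table: ObservationTable, traits: Sequence[TraitSpec],
                      trial_as_factor: bool = True,
                      starts=None, **fit_kwargs) -> HierarchyResult:
    """Fit the nested model hierarchy and tabulate likelihood-ratio tests.

    For ``k`` traits the comparisons add ``k`` among-individual
    variances (1 vs 2), ``k(k-1)/2`` within-individual covariances
    (2 vs 3) and ``k(k-1)/2`` among-individual covariances (3 vs 4).
    Multivariate comparisons use the conservative plain chi-square; the
    univariate case (k = 1) tests its single boundary variance with the
    half-mixture.
    """
    traits = tuple(traits)
    k = len(traits)
    specs = _model_specs(traits, trial_as_factor)
    if starts is not None:
        fit_kwargs["starts"] = starts
    fits = {m: reml_fit(table, s, **fit_kwargs) for m, s in specs.items()}

    rows = []
    if k == 1:
        q = 2.0 * (fits[2].reml_loglik - fits[1].reml_loglik)
        res = lrt_pvalue(max(q, 0.0), df=1, mixture="half_chisq")
        rows.append(("1 vs 2", res.statistic, res.df, res.mixture, res.p_value))
    else:
        pairs = [("1 vs 2", 1, 2, k),
                 ("2 vs 3", 2, 3, k * (k - 1) // 2),
                 ("3 vs 4", 3, 4, k * (k - 1) // 2)]
        for label, a, b, df in pairs:
            q = 2.0 * (fits[b].reml_loglik - fits[a].reml_loglik)
            res = lrt_pvalue(max(q, 0.0), df=df, mixture="none")
            rows.append((label, res.statistic, res.df, res.mixture, res.p_value))
    tests = pd.DataFrame(rows, columns=["comparison", "statistic", "df",
                                        "mixture", "p_value"])
    return HierarchyResult(fits=fits, tests=tests)


# ---------------------------------------------------------------------------
# Correlations and repeatability


def corr_from_cov(cov: np.ndarray, warn_out_of_range: bool = True) -> np.ndarray:
    """Correlation matrix ``r_xy = cov_xy / sqrt(v_x v_y)``.

    Estimated covariance matrices need not be positive definite, so
    off-diagonal values can fall outside [-1, 1]; these are returned
    as computed (with a warning) rather than truncated.
    """
    cov = np.asarray(cov, dtype=float)
    d = np.diag(cov)
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal entry in covariance matrix")
    s = np.sqrt(d)
    corr = cov / np.outer(s, s)
    np.fill_diagonal(corr, 1.0)
    off = corr[~np.eye(len(corr), dtype=bool)]
    if warn_out_of_range and np.any(np.abs(off) > 1.0):
        warnings.warn("correlation outside [-1, 1]; input matrix is not PSD",
                      stacklevel=2)
    return corr


def repeatability(fit: CovarianceFit, trait: str):
    """Repeatability of one trait with a delta-method standard error.

    Returns ``V_I / (V_I + V_R)``, the proportion of phenotypic
    variance explained by individual identity.  For traits analyzed in
    standard-deviation units this equals ``V_I`` up to the (estimated)
    total variance being 1.
    """
    if fit.spec.I_structure == "absent":
        raise ValueError("model has no among-individual component")
    t = fit.trait_names.index(trait)
    v_i = float(fit.I_hat[t, t])
    v_r = float(fit.R_hat[t, t])
    rep = v_i / (v_i + v_r)

    # delta method on (V_I, V_R) using the joint sampling covariance
    S = fit.sampling_cov("both")
    k = len(fit.trait_names)
    nv = k * (k + 1) // 2
    idx_ii = t * (t + 1) // 2 + t        # position of (t, t) in vech
    ii = idx_ii
    rr = nv + idx_ii
    tot = v_i + v_r
    gradv = np.zeros(2 * nv)
    gradv[ii] = v_r / tot ** 2
    gradv[rr] = -v_i / tot ** 2
    var = float(gradv @ S @ gradv)
    return rep, float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Auxiliary analyses


def _residualize(values: np.ndarray, covariates: Optional[np.ndarray]):
    mask = np.isfinite(values)
    if covariates is not None:
        mask &= np.all(np.isfinite(covariates), axis=1)
    out = np.full_like(values, np.nan, dtype=float)
    if covariates is None:
        out[mask] = values[mask] - values[mask].mean()
        return out
    X = np.column_stack([np.ones(mask.sum()), covariates[mask]])
    coef, *_ = np.linalg.lstsq(X, values[mask], rcond=None)
    out[mask] = values[mask] - X @ coef
    return out


def _pearson_with_se(x: np.ndarray, y: np.ndarray):
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        raise DataError("need >= 3 complete pairs for a correlation")
    r = float(np.corrcoef(x[mask], y[mask])[0, 1])
    se = float(np.sqrt((1.0 - r ** 2) / (n - 2)))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return r, se, p, n


def between_trial_correlations(table: ObservationTable, trait: str,
                               covariates: Sequence[str] = ("mass", "day_order"),
                               transform: str = "ln"):
    """Trial-by-trial correlation matrix of one trait across individuals.

    Each trial's values are first residualized on the named covariates
    by least squares, then Pearson correlations are computed across
    individuals for every trial pair (pairwise-complete).  Standard
    errors are the classical ``sqrt((1 - r^2)/(n - 2))``; entries with
    ``|r| >= 2 SE`` are flagged significant.
    """
    from .data_model import transform_series

    df = table.data
    trials = sorted(df["trial_number"].unique())
    wide = {}
    for tr in trials:
        sub = df[df["trial_number"] == tr].set_index("individual_id")
        vals = transform_series(sub[trait], transform).to_numpy(float)
        covs = (sub[list(covariates)].to_numpy(float)
                if covariates else None)
        wide[tr] = pd.Series(_residualize(vals, covs), index=sub.index)
    wide = pd.DataFrame(wide)

    T = len(trials)
    r = np.full((T, T), np.nan)
    se = np.full((T, T), np.nan)
    sig = np.zeros((T, T), dtype=bool)
    np.fill_diagonal(r, 1.0)
    for a in range(T):
        for b in range(a + 1, T):
            ra, sea, _, _ = _pearson_with_se(
                wide[trials[a]].to_numpy(), wide[trials[b]].to_numpy())
            r[a, b] = r[b, a] = ra
            se[a, b] = se[b, a] = sea
            sig[a, b] = sig[b, a] = abs(ra) >= 2.0 * sea
    labels = [f"T{t}" for t in trials]
    return (pd.DataFrame(r, index=labels, columns=labels),
            pd.DataFrame(se, index=labels, columns=labels),
            pd.DataFrame(sig, index=labels, columns=labels))


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    df: int
    p_value: float
    mean_difference: float
    n_pairs: int


def paired_mean_change(pre, post) -> PairedTestResult:
    """Paired t-test of pre- vs post-trial values (one-sample t on pre - post)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (same length)")
    mask = np.isfinite(pre) & np.isfinite(post)
    d = pre[mask] - post[mask]
    n = len(d)
    if n < 2:
        raise DataError("need >= 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return PairedTestResult(0.0, n - 1, 1.0, 0.0, n)
        raise DataError("zero-variance differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTestResult(t, n - 1, p, float(d.mean()), n)


def validation_correlation(waterborne, whole_body, masses):
    """Correlation of ln mass-scaled waterborne vs whole-body hormone levels.

    Both measures are divided by body mass and natural-log-transformed
    before the Pearson correlation, mirroring how a noninvasive holding
    -water assay is validated against whole-body extraction.
    Returns ``(r, se, p, n)``.
    """
    from .data_model import mass_adjust_ln

    w = np.asarray(waterborne, dtype=float)
    b = np.asarray(whole_body, dtype=float)
    m = np.asarray(masses, dtype=float)
    lw = mass_adjust_ln(w, m)
    lb = mass_adjust_ln(b, m)
    return _pearson_with_se(lw, lb)
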