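"""Simulate repeated-measures stress-response datasets.

The generator emulates the design the analysis pipeline assumes: 20
male swordtails (*Xiphophorus birchmanni*) each given five open-field
trials at 4-day intervals, with five behavioral scores per trial, a
binary post-strike emergence outcome, and four waterborne steroid
release rates (cortisol and 11-ketotestosterone, pre- and post-trial).

Traits are generated on the transformed standard-deviation-unit scale
as

    y*_ijt = fixed effects + u_it + e_ijt,
    u_i ~ MVN(0, I),  e_ij ~ MVN(0, R),

with ``I`` the among-individual and ``R`` the within-individual
covariance matrix, and then *back-transformed* (squared for behaviors,
exponentiated for hormones) onto a raw scale with realistic locations,
so the full pipeline — transform, SD-scaling, REML — is exercised end
to end.  The default ``I`` and ``R`` are the empirical estimates for
this population (behaviors) or are assembled from published
repeatabilities and correlations (hormones).

The binary emergence trait comes from a latent liability: a Gaussian
individual effect plus a unit-variance Gaussian trial deviate, pushed
through a logistic link (so the implicit logistic residual contributes
pi^2/3 of latent variance, matching the threshold model used for
analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._linalg import nearest_psd
from .data_model import (
    BEHAVIOR_NAMES,
    HORMONE_NAMES,
    BEHAVIOR_TRAITS,
    HORMONE_TRAITS,
    ObservationTable,
    TraitSpec,
)

__all__ = [
    "BEHAVIOR_I_REFERENCE",
    "BEHAVIOR_R_REFERENCE",
    "HORMONE_I_DEFAULT",
    "HORMONE_R_DEFAULT",
    "LiabilitySpec",
    "SimulationDesign",
    "make_rank1_I",
    "simulate_study",
]

# Empirical among-individual (I) and within-individual (R) covariance
# matrices for the five open-field behaviors (TL, ACT, AC, TIM, TOR),
# traits in standard-deviation units.  These serve as the generator's
# default truth; I is projected to the nearest PSD matrix because the
# printed estimate is marginally indefinite (smallest eigenvalue -3e-5).
BEHAVIOR_I_REFERENCE = np.array([
    [0.274, 0.285, 0.237, 0.140, 0.253],
    [0.285, 0.305, 0.246, 0.158, 0.277],
    [0.237, 0.246, 0.217, 0.127, 0.219],
    [0.140, 0.158, 0.127, 0.101, 0.149],
    [0.253, 0.277, 0.219, 0.149, 0.256],
])

BEHAVIOR_R_REFERENCE = np.array([
    [0.722, 0.696, 0.680, 0.502, 0.681],
    [0.696, 0.695, 0.658, 0.516, 0.682],
    [0.680, 0.658, 0.769, 0.656, 0.658],
    [0.502, 0.516, 0.656, 0.872, 0.534],
    [0.681, 0.682, 0.658, 0.534, 0.726],
])


def _hormone_defaults():
    # Diagonals are the reported repeatabilities (F_PRE, F_POST,
    # KT11_PRE, KT11_POST); the single among-individual correlation with
    # empirical support is F_PRE-KT11_PRE (r_I = 0.768) and the single
    # within-individual one is F_POST-KT11_POST (r_R = 0.356).
    v_i = np.array([0.10, 0.039, 0.202, 0.05])
    I = np.diag(v_i)
    I[0, 2] = I[2, 0] = 0.768 * np.sqrt(v_i[0] * v_i[2])
    v_r = 1.0 - v_i
    R = np.diag(v_r)
    R[1, 3] = R[3, 1] = 0.356 * np.sqrt(v_r[1] * v_r[3])
    return I, R


HORMONE_I_DEFAULT, HORMONE_R_DEFAULT = _hormone_defaults()

# Raw-scale anchors for back-transformation: (location, scale) of each
# trait on its transformed scale.  Locations give realistic raw means
# (e.g. track length ~900 cm, pre-trial cortisol ~1871 pg/h); scales
# are the raw-data SDs on the transformed scale, which the pipeline's
# SD-unit rescaling later divides back out.
RAW_ANCHORS = {
    "TL": (30.0, 3.0),
    "ACT": (6.0, 0.6),
    "AC": (7.0, 0.7),
    "TIM": (4.0, 0.8),
    "TOR": (8.0, 1.0),
    "F_PRE": (np.log(1871.0), 0.9),
    "F_POST": (np.log(669.0), 0.9),
    "KT11_PRE": (np.log(105.6), 0.45),
    "KT11_POST": (np.log(99.7), 0.45),
}


@dataclass(frozen=True)
class LiabilitySpec:
    """Latent-liability generator for the binary emergence trait.

    ``intercept`` sets prevalence (about one-third of trials end in
    re-emergence at the default), ``v_individual`` is the
    among-individual variance on the liability scale, and
    ``gaussian_resid_var`` the Gaussian trial-level residual variance
    (1.0 matches the analysis model, which fixes it at 1; the logistic
    link itself adds a further pi^2/3).  ``corr_with_trait`` couples the
    liability individual effect to the individual effect of one
    Gaussian trait, so that emergent fish tend to be the bold ones.
    """

    intercept: float = -0.8
    v_individual: float = 1.0
    gaussian_resid_var: float = 1.0
    corr_with_trait: Optional[str] = "ACT"
    corr: float = 0.4


@dataclass
class SimulationDesign:
    """Full specification of one simulated study."""

    n_individuals: int = 20
    n_trials: int = 5
    traits: Sequence[TraitSpec] = field(
        default_factory=lambda: tuple(BEHAVIOR_TRAITS) + tuple(HORMONE_TRAITS))
    I_true: np.ndarray = None
    R_true: np.ndarray = None
    trial_effects: Optional[np.ndarray] = None   # (n_trials,) added per trial, SD units
    stack_effect: float = 0.0
    day_order_slope: float = 0.0
    mass_slope: float = 0.0                      # hormones only, per mean-centered gram
    mass_mean: float = 1.16
    mass_sd: float = 0.073
    liability: Optional[LiabilitySpec] = field(default_factory=LiabilitySpec)
    # One randomly chosen fish is absent from the final trial, mirroring
    # the death of one animal between trials four and five.
    drop_one_last_trial: bool = True
    seed: Optional[int] = None

    def __post_init__(self):
        k = len(self.traits)
        if self.I_true is None or self.R_true is None:
            names = [t.name for t in self.traits]
            if names == BEHAVIOR_NAMES + HORMONE_NAMES:
                I = np.zeros((k, k))
                R = np.zeros((k, k))
                I[:5, :5] = nearest_psd(BEHAVIOR_I_REFERENCE)
                I[5:, 5:] = HORMONE_I_DEFAULT
                R[:5, :5] = BEHAVIOR_R_REFERENCE
                R[5:, 5:] = HORMONE_R_DEFAULT
            elif names == BEHAVIOR_NAMES:
                I = nearest_psd(BEHAVIOR_I_REFERENCE)
                R = BEHAVIOR_R_REFERENCE.copy()
            elif names == HORMONE_NAMES:
                I, R = HORMONE_I_DEFAULT.copy(), HORMONE_R_DEFAULT.copy()
            else:
                raise ValueError(
                    "I_true/R_true must be given for a custom trait list")
            if self.I_true is None:
                self.I_true = I
            if self.R_true is None:
                self.R_true = R
        self.I_true = np.asarray(self.I_true, dtype=float)
        self.R_true = np.asarray(self.R_true, dtype=float)
        if self.I_true.shape != (k, k) or self.R_true.shape != (k, k):
            raise ValueError("covariance dimensions do not match trait list")
        if np.min(np.linalg.eigvalsh(0.5 * (self.I_true + self.I_true.T))) < -1e-10:
            raise ValueError("I_true must be positive semidefinite")
        if np.min(np.linalg.eigvalsh(0.5 * (self.R_true + self.R_true.T))) <= 1e-12:
            raise ValueError("R_true must be positive definite")
        if self.trial_effects is not None:
            self.trial_effects = np.asarray(self.trial_effects, dtype=float)
            if len(self.trial_effects) != self.n_trials:
                raise ValueError("trial_effects length must equal n_trials")


def make_rank1_I(loadings, noise: float = 0.0) -> np.ndarray:
    """Rank-1 among-individual covariance ``v v^T + noise * identity``.

    With ``noise=0`` the first eigenvector carries 100% of the variance
    — the idealized single-axis (personality) structure.
    """
    v = np.asarray(loadings, dtype=float)
    if v.size == 0:
        raise ValueError("loadings must be non-empty")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    return np.outer(v, v) + noise * np.eye(v.size)


def _back_transform(name: str, spec: TraitSpec, y_star: np.ndarray) -> np.ndarray:
    loc, scale = RAW_ANCHORS.get(name, (0.0, 1.0))
    t = loc + scale * y_star
    if spec.transform == "sqrt":
        t = np.clip(t, 0.0, None)
        raw = t ** 2
        if name in ("ACT", "AC"):
            raw = np.clip(raw, 0.0, 100.0)
        return raw
    if spec.transform == "ln":
        return np.exp(t)
    return t


def simulate_study(design: SimulationDesign) -> ObservationTable:
    """Draw one complete dataset; deterministic given ``design.seed``."""
    rng = np.random.default_rng(design.seed)
    n, T = design.n_individuals, design.n_trials
    traits = list(design.traits)
    k = len(traits)
    names = [t.name for t in traits]

    ids = [f"F{i+1:02d}" for i in range(n)]
    stack = np.array(["A" if i < n // 2 else "B" for i in range(n)])
    mass = rng.normal(design.mass_mean, design.mass_sd, size=n)
    mass = np.clip(mass, 0.5 * design.mass_mean, None)
    mass_c = mass - mass.mean()

    u = rng.multivariate_normal(np.zeros(k), design.I_true, size=n,
                                method="eigh")                      # (n, k)
    rows = []
    trial_eff = (design.trial_effects if design.trial_effects is not None
                 else np.zeros(T))

    # emergence liability individual effect, optionally coupled to one
    # Gaussian trait's individual effect
    lia = design.liability
    u_liab = np.zeros(n)
    if lia is not None and lia.v_individual > 0:
        indep = rng.normal(0.0, 1.0, size=n)
        if lia.corr_with_trait in names and lia.corr != 0.0:
            j = names.index(lia.corr_with_trait)
            sd_j = np.sqrt(design.I_true[j, j])
            z = u[:, j] / sd_j if sd_j > 0 else indep
            u_liab = np.sqrt(lia.v_individual) * (
                lia.corr * z + np.sqrt(1.0 - lia.corr ** 2) * indep)
        else:
            u_liab = np.sqrt(lia.v_individual) * indep

    for j in range(T):
        day_order = rng.permutation(n)          # testing order that day
        do_c = day_order - day_order.mean()
        e = rng.multivariate_normal(np.zeros(k), design.R_true, size=n,
                                    method="cholesky")
        for i in range(n):
            y_star = u[i] + e[i] + trial_eff[j]
            y_star = y_star + (design.stack_effect if stack[i] == "B" else 0.0)
            y_star = y_star + design.day_order_slope * do_c[i]
            row = {
                "individual_id": ids[i],
                "trial_number": j + 1,
                "day_order": int(day_order[i]),
                "stack": stack[i],
                "mass": round(float(mass[i]), 4),
            }
            for t_idx, spec in enumerate(traits):
                val = y_star[t_idx]
                if spec.transform == "ln":
                    val = val + design.mass_slope * mass_c[i]
                row[spec.name] = float(
                    _back_transform(spec.name, spec, np.asarray(val)))
            if lia is not None:
                liab = (lia.intercept + u_liab[i]
                        + rng.normal(0.0, np.sqrt(lia.gaussian_resid_var))
                        if lia.gaussian_resid_var > 0
                        else lia.intercept + u_liab[i])
                row["emREF"] = int(rng.random() < expit(liab))
            rows.append(row)

    df = pd.DataFrame(rows)
    if design.drop_one_last_trial and T >= 2:
        victim = ids[int(rng.integers(n))]
        df = df[~((df["individual_id"] == victim)
                  & (df["trial_number"] == T))].reset_index(drop=True)
    return ObservationTable(df)
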