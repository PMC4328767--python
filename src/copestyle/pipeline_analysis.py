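"""End-to-end orchestration of the repeated-measures stress-response analysis.

One call runs the four analysis blocks on an observation table:

* **behavior** — the four-model hierarchy over the five open-field
  behaviors, likelihood-ratio tests, the I/R matrix report, and the
  eigen decomposition of I with bootstrapped EV1 loadings;
* **emergence** — the liability-scale repeatability of the binary
  emergence trait and its among-individual correlations with each
  baseline behavior (bivariate binary-Gaussian models);
* **endocrine** — the same hierarchy over the four hormone release
  rates plus paired pre/post mean-change tests;
* **integration** — the trivariate model of activity (the univariate
  boldness proxy) with pre-trial cortisol and 11-ketotestosterone,
  testing whether behavioral and endocrine variation share an
  among-individual axis;

plus the between-trial correlation matrix of pre-trial cortisol.  All
stochastic stages are seeded from one master seed, so a rerun with the
same data, config and seed reproduces the report bit for bit.  A
failing stage is recorded with its error; independent stages still run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .data_model import (BEHAVIOR_NAMES, BEHAVIOR_TRAITS, HORMONE_TRAITS,
                         ObservationTable, behavior_spec, hormone_spec)
from .eigen_boot import bootstrap_loadings
from .inference import (between_trial_correlations, compare_hierarchy,
                        corr_from_cov, paired_mean_change, repeatability)
from .liability import (FULL_SETTINGS, TEST_SETTINGS, fit_binary_liability,
                        fit_bivariate_binary_gaussian)

__all__ = ["AnalysisConfig", "AnalysisReport", "cov_corr_table",
           "run_full_analysis", "write_report"]

_ALL_STAGES = ("behavior", "emergence", "endocrine", "integration",
               "between_trial")


@dataclass
class AnalysisConfig:
    seed: int = 0
    stages: Sequence[str] = _ALL_STAGES
    mcmc_preset: str = "test"              # 'test' or 'full'
    n_boot_draws: int = 5000
    emergence_partners: Sequence[str] = tuple(BEHAVIOR_NAMES)
    boldness_proxy: str = "ACT"
    between_trial_trait: str = "F_PRE"
    reml_starts: Optional[Sequence[float]] = None

    def mcmc_settings(self):
        return FULL_SETTINGS if self.mcmc_preset == "full" else TEST_SETTINGS

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["emergence_partners"] = list(self.emergence_partners)
        d["reml_starts"] = (list(self.reml_starts)
                            if self.reml_starts is not None else None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        for key in ("stages", "emergence_partners"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("reml_starts") is not None:
            kwargs["reml_starts"] = tuple(kwargs["reml_starts"])
        return cls(**kwargs)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    blocks: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def cov_corr_table(M: np.ndarray, trait_names, se: Optional[np.ndarray] = None
                   ) -> pd.DataFrame:
    """Matrix report: variances on the diagonal, covariances below it,
    correlations above it."""
    M = np.asarray(M, float)
    k = M.shape[0]
    corr = corr_from_cov(M, warn_out_of_range=False) \
        if np.all(np.diag(M) > 0) else np.full_like(M, np.nan)
    out = np.where(np.triu(np.ones((k, k), bool), 1), corr, M)
    return pd.DataFrame(out, index=trait_names, columns=trait_names)


def _stage_seeds(master_seed: int, n: int = 8):
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _fit_kwargs(config: AnalysisConfig) -> dict:
    return ({"starts": tuple(config.reml_starts)}
            if config.reml_starts is not None else {})


def run_full_analysis(table: ObservationTable,
                      config: AnalysisConfig = None) -> AnalysisReport:
    config = config or AnalysisConfig()
    seeds = _stage_seeds(config.seed)
    report = AnalysisReport()
    settings = config.mcmc_settings()
    fk = _fit_kwargs(config)

    def run_stage(name, fn):
        if name not in config.stages:
            return
        try:
            report.blocks[name] = fn()
        except Exception as exc:      # noqa: BLE001 - stage isolation
            report.errors[name] = f"{type(exc).__name__}: {exc}"

    # -- behavior ----------------------------------------------------------
    def behavior():
        hier = compare_hierarchy(table, BEHAVIOR_TRAITS, **fk)
        fit4 = hier.fit(4)
        S = fit4.sampling_cov("I")
        boot = bootstrap_loadings(fit4.I_hat, S, n_draws=config.n_boot_draws,
                                  seed=seeds[0],
                                  trait_names=fit4.trait_names)
        reps = {t: repeatability(fit4, t) for t in fit4.trait_names}
        return {
            "model_spec": {m: (f.spec.I_structure, f.spec.R_structure)
                           for m, f in hier.fits.items()},
            "lrt": hier.tests,
            "I_report": cov_corr_table(fit4.I_hat, fit4.trait_names),
            "R_report": cov_corr_table(fit4.R_hat, fit4.trait_names),
            "repeatability": pd.DataFrame(
                {t: {"estimate": r, "se": s} for t, (r, s) in reps.items()}).T,
            "eigen": boot,
            "fit4": fit4,
        }
    run_stage("behavior", behavior)

    # -- emergence ---------------------------------------------------------
    def emergence():
        uni = fit_binary_liability(table, settings=settings, seed=seeds[1])
        rows = []
        for i, partner in enumerate(config.emergence_partners):
            post = fit_bivariate_binary_gaussian(
                table, gaussian_trait=behavior_spec(partner),
                settings=settings, seed=seeds[2] + i)
            lo, hi = post.hpd("r_I")
            rows.append({"trait": partner,
                         "r_I": float(np.mean(post.chains["r_I"])),
                         "hpd_lower": lo, "hpd_upper": hi})
        return {
            "liability": uni,
            "icc_summary": uni.summary().loc["icc"],
            "r_I_table": pd.DataFrame(rows).set_index("trait"),
        }
    run_stage("emergence", emergence)

    # -- endocrine ---------------------------------------------------------
    def endocrine():
        hier = compare_hierarchy(table, HORMONE_TRAITS, **fk)
        fit4 = hier.fit(4)
        reps = {t: repeatability(fit4, t) for t in fit4.trait_names}
        df = table.data
        paired = {}
        for pre, post in (("F_PRE", "F_POST"), ("KT11_PRE", "KT11_POST")):
            res = paired_mean_change(df[pre].to_numpy(), df[post].to_numpy())
            paired[f"{pre} vs {post}"] = res
        return {
            "lrt": hier.tests,
            "I_report": cov_corr_table(fit4.I_hat, fit4.trait_names),
            "R_report": cov_corr_table(fit4.R_hat, fit4.trait_names),
            "repeatability": pd.DataFrame(
                {t: {"estimate": r, "se": s} for t, (r, s) in reps.items()}).T,
            "paired_tests": paired,
            "fit4": fit4,
        }
    run_stage("endocrine", endocrine)

    # -- integration -------------------------------------------------------
    def integration():
        traits = (behavior_spec(config.boldness_proxy),
                  hormone_spec("F_PRE"), hormone_spec("KT11_PRE"))
        hier = compare_hierarchy(table, traits, **fk)
        fit4 = hier.fit(4)
        return {
            "lrt": hier.tests,
            "I_report": cov_corr_table(fit4.I_hat, fit4.trait_names),
            "R_report": cov_corr_table(fit4.R_hat, fit4.trait_names),
            "r_I": corr_from_cov(fit4.I_hat, warn_out_of_range=False)
            if np.all(np.diag(fit4.I_hat) > 0) else None,
            "fit4": fit4,
        }
    run_stage("integration", integration)

    # -- between-trial correlations ---------------------------------------
    def between_trial():
        r, se, sig = between_trial_correlations(
            table, config.between_trial_trait,
            covariates=("mass", "day_order"), transform="ln")
        return {"r": r, "se": se, "significant": sig}
    run_stage("between_trial", between_trial)

    import scipy
    report.provenance = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "versions": {"copestyle": _pkg_version, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
    }
    return report


# ---------------------------------------------------------------------------
# Report serialization


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(report: AnalysisReport, outdir) -> None:
    """Write the report as a directory of delimited-text tables plus a
    machine-readable summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"errors": report.errors, "provenance": report.provenance,
               "blocks": {}}

    for stage, block in report.blocks.items():
        s = {}
        for key, val in block.items():
            if isinstance(val, pd.DataFrame):
                val.to_csv(out / f"{stage}_{key}.csv")
            elif isinstance(val, pd.Series):
                s[key] = _jsonify(val.to_dict())
            elif key == "eigen":
                eig = pd.DataFrame({
                    "loading_EV1": val.ev1,
                    "hpd_lower": val.hpd_lower,
                    "hpd_upper": val.hpd_upper,
                }, index=val.trait_names)
                eig.to_csv(out / f"{stage}_ev1_loadings.csv")
                s["ev1_share_pct"] = float(val.ev1_share)
                s["eigenvalues"] = _jsonify(val.eigenvalues)
                s["share_of_draws_nonPD"] = val.share_of_draws_nonPD
            elif key == "liability":
                pd.DataFrame(val.chains).to_csv(
                    out / f"{stage}_chains.csv", index=False)
                s["icc_mode"] = float(val.summary().loc["icc", "mode"])
                s["icc_hpd"] = list(val.hpd("icc"))
            elif key == "paired_tests":
                s[key] = {k: {"t": v.statistic, "df": v.df, "p": v.p_value,
                              "mean_difference": v.mean_difference}
                          for k, v in val.items()}
            elif key == "fit4":
                s["reml_loglik_model4"] = val.reml_loglik
                s["boundary_traits"] = val.boundary_traits
            elif key == "r_I" and val is not None:
                s[key] = _jsonify(val)
            elif isinstance(val, (int, float, str, dict, list, tuple)):
                s[key] = _jsonify(val)
        summary["blocks"][stage] = s

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonify(summary), fh, indent=2)
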