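import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copestyle.data_model import (BEHAVIOR_TRAITS, DataError,
                                  ObservationTable, TraitSpec)
from copestyle.mvmm import (ModelSpec, build_design, reml_fit,
                            reml_loglik_at, reml_loglik_oracle)
from copestyle.synthetic_data import SimulationDesign, simulate_study


def _uni_spec(plain_trait, I="diagonal", R="diagonal"):
    return ModelSpec(traits=(plain_trait,), I_structure=I, R_structure=R)


class TestClosedForms:
    def test_balanced_one_way_equals_anova(self, balanced_table, plain_trait):
        fit = reml_fit(balanced_table, _uni_spec(plain_trait))
        assert fit.V_I("y") == pytest.approx(6.0, abs=1e-5)
        assert fit.V_R("y") == pytest.approx(2.0, abs=1e-5)
        assert fit.converged and not fit.boundary

    def test_no_individual_effect_gives_sample_variance(self, plain_trait):
        tab = ObservationTable(pd.DataFrame({
            "individual_id": ["A", "B", "C"], "trial_number": [1, 1, 1],
            "y": [1.0, 2.0, 3.0]}))
        fit = reml_fit(tab, _uni_spec(plain_trait, I="absent"))
        assert fit.V_R("y") == pytest.approx(1.0, abs=1e-6)

    def test_zero_between_variance_hits_boundary(self, plain_trait):
        # identical individual means: MSB = 0 => V_I on the boundary
        tab = ObservationTable(pd.DataFrame({
            "individual_id": list("AABBCC"), "trial_number": [1, 2] * 3,
            "y": [1.0, 9.0, 2.0, 8.0, 3.0, 7.0]}))
        fit = reml_fit(tab, _uni_spec(plain_trait))
        assert fit.boundary and fit.V_I("y") == 0.0

    @given(st.integers(0, 10_000))
    def test_balanced_reml_matches_anova_estimators(self, seed):
        plain_trait = TraitSpec(name="y", transform="none",
                                scale_to_sd=False, fixed_effects=("mean",))
        rng = np.random.default_rng(seed)
        n_ind, n_rep = 5, 3
        y = (rng.normal(0, 2, n_ind).repeat(n_rep)
             + rng.normal(0, 1, n_ind * n_rep))
        df = pd.DataFrame({
            "individual_id": np.repeat([f"i{j}" for j in range(n_ind)], n_rep),
            "trial_number": np.tile(np.arange(1, n_rep + 1), n_ind),
            "y": y})
        groups = df.groupby("individual_id")["y"]
        msb = n_rep * groups.mean().var(ddof=1)
        msw = groups.var(ddof=1).mean()
        fit = reml_fit(ObservationTable(df), _uni_spec(plain_trait))
        if msb > msw:  # interior solution: REML == ANOVA
            assert fit.V_I("y") == pytest.approx((msb - msw) / n_rep,
                                                 rel=1e-4, abs=1e-6)
            assert fit.V_R("y") == pytest.approx(msw, rel=1e-4)
        else:
            assert fit.V_I("y") == 0.0


class TestOracle:
    def test_stationary_at_closed_form_solution(self, balanced_table,
                                                plain_trait):
        spec = _uni_spec(plain_trait)
        I0, R0 = np.array([[6.0]]), np.array([[2.0]])

        def f(vi, vr):
            return reml_loglik_oracle(balanced_table, spec, [[vi]], [[vr]])

        h = 1e-5
        g_i = (f(6 + h, 2) - f(6 - h, 2)) / (2 * h)
        g_r = (f(6, 2 + h) - f(6, 2 - h)) / (2 * h)
        assert abs(g_i) < 1e-4 and abs(g_r) < 1e-4
        assert reml_loglik_at(balanced_table, spec, I0, R0) == pytest.approx(
            reml_loglik_oracle(balanced_table, spec, I0, R0), abs=1e-9)

    def test_reduces_to_iid_gaussian_when_I_zero(self, balanced_table,
                                                 plain_trait):
        from scipy import stats
        spec = _uni_spec(plain_trait, I="absent")
        ll = reml_loglik_oracle(balanced_table, spec, np.zeros((1, 1)),
                                [[2.0]])
        y = balanced_table.data["y"].to_numpy()
        resid = y - y.mean()
        direct = (np.sum(stats.norm.logpdf(resid, scale=np.sqrt(2.0)))
                  - 0.5 * np.log(len(y) / (2 * np.pi * 2.0)))
        assert ll == pytest.approx(direct, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_optimizer_loglik_matches_oracle(self, seed):
        """Randomized small instances: block-wise and brute-force REML
        log-likelihoods agree at (and away from) the optimum."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 3))
        traits = tuple(
            TraitSpec(name=f"t{j}", transform="none", scale_to_sd=False,
                      fixed_effects=("mean",)) for j in range(k))
        I_s = ["absent", "diagonal", "unstructured"][seed % 3]
        R_s = ["diagonal", "unstructured"][seed % 2]
        n_ind, n_tr = 5, 3
        rows = []
        for i in range(n_ind):
            for t in range(n_tr):
                if rng.random() < 0.15:
                    continue
                row = {"individual_id": f"i{i}", "trial_number": t + 1}
                for j in range(k):
                    row[f"t{j}"] = rng.normal(0, 1) + 0.7 * i / n_ind
                rows.append(row)
        tab = ObservationTable(pd.DataFrame(rows))
        spec = ModelSpec(traits=traits, I_structure=I_s, R_structure=R_s)
        fit = reml_fit(tab, spec)
        assert fit.reml_loglik == pytest.approx(
            reml_loglik_oracle(tab, spec, fit.I_hat, fit.R_hat), abs=1e-6)
        # also at a perturbed, non-optimal point
        I_p = fit.I_hat + 0.1 * np.eye(k)
        R_p = fit.R_hat + 0.2 * np.eye(k)
        assert reml_loglik_at(tab, spec, I_p, R_p) == pytest.approx(
            reml_loglik_oracle(tab, spec, I_p, R_p), abs=1e-6)

    def test_scale_equivariance(self, balanced_table, plain_trait):
        spec = _uni_spec(plain_trait)
        fit1 = reml_fit(balanced_table, spec)
        df2 = balanced_table.data.copy()
        df2["y"] = 2.0 * df2["y"]
        fit2 = reml_fit(ObservationTable(df2), spec)
        assert fit2.V_I("y") == pytest.approx(4 * fit1.V_I("y"), rel=1e-4)
        assert fit2.V_R("y") == pytest.approx(4 * fit1.V_R("y"), rel=1e-4)
        n, p = fit1.n_obs, 1
        assert (fit2.reml_loglik - fit1.reml_loglik
                == pytest.approx(-(n - p) * np.log(2.0), abs=1e-5))


class TestMultivariate:
    def test_nested_models_ordered(self, behavior_table):
        lls = []
        for I_s, R_s in [("absent", "diagonal"), ("diagonal", "diagonal"),
                         ("diagonal", "unstructured"),
                         ("unstructured", "unstructured")]:
            spec = ModelSpec(traits=BEHAVIOR_TRAITS, I_structure=I_s,
                             R_structure=R_s)
            lls.append(reml_fit(behavior_table, spec,
                                starts=(0.3,)).reml_loglik)
        assert all(lls[i] <= lls[i + 1] + 1e-6 for i in range(3))

    def test_loglik_invariant_to_trait_order(self, behavior_table):
        spec_a = ModelSpec(traits=BEHAVIOR_TRAITS[:2])
        spec_b = ModelSpec(traits=BEHAVIOR_TRAITS[:2][::-1])
        fa = reml_fit(behavior_table, spec_a, starts=(0.3,))
        fb = reml_fit(behavior_table, spec_b, starts=(0.3,))
        assert fa.reml_loglik == pytest.approx(fb.reml_loglik, abs=1e-5)
        assert fa.I_hat[0, 1] == pytest.approx(fb.I_hat[1, 0], abs=1e-3)

    def test_sampling_cov_symmetric_psd(self, behavior_table):
        spec = ModelSpec(traits=BEHAVIOR_TRAITS[:3])
        fit = reml_fit(behavior_table, spec, starts=(0.3,))
        S = fit.sampling_cov("I")
        assert S.shape == (6, 6)
        assert np.allclose(S, S.T)
        assert np.min(np.linalg.eigvalsh(S)) > -1e-8


class TestDesign:
    def test_response_length_and_centering(self):
        tab = simulate_study(SimulationDesign(
            traits=BEHAVIOR_TRAITS, seed=1, drop_one_last_trial=False,
            liability=None))
        spec = ModelSpec(traits=BEHAVIOR_TRAITS)
        des = build_design(tab, spec)
        assert des.n_obs == 20 * 5 * 5
        day_cols = [i for i, c in enumerate(des.col_names)
                    if c.endswith("day_order")]
        for c in day_cols:
            col = des.X[:, c]
            assert abs(col[col != 0].sum()) < 1e-8 or abs(col.sum()) < 1e-8

    def test_missing_covariate_column_errors(self, behavior_table):
        tspec = TraitSpec(name="TL", transform="sqrt",
                          fixed_effects=("mean", "mass"))
        spec = ModelSpec(traits=(tspec,))
        df = behavior_table.data.drop(columns=["mass"], errors="ignore")
        with pytest.raises(DataError, match="mass"):
            build_design(ObservationTable(df), spec)

    def test_single_level_factor_errors(self, plain_trait):
        df = pd.DataFrame({
            "individual_id": list("AABB"), "trial_number": [1, 2, 1, 2],
            "stack": ["A"] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        tspec = TraitSpec(name="y", transform="none", scale_to_sd=False,
                          fixed_effects=("mean", "stack"))
        with pytest.raises(DataError, match="single level"):
            build_design(ObservationTable(df), ModelSpec(traits=(tspec,)))
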