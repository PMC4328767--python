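import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copestyle.data_model import ObservationTable, TraitSpec
from copestyle.inference import (between_trial_correlations,
                                 compare_hierarchy, corr_from_cov,
                                 lrt_pvalue, paired_mean_change,
                                 repeatability, validation_correlation)
from copestyle.mvmm import ModelSpec, reml_fit
from copestyle.synthetic_data import BEHAVIOR_I_REFERENCE


class TestLRT:
    def test_large_statistic_multivariate(self):
        # global test of among-individual variance over five traits
        res = lrt_pvalue(32.9, df=5, mixture="none")
        assert res.p_value == pytest.approx(4.0e-6, abs=1.5e-6)
        assert res.p_value < 0.001

    def test_null_statistic_is_one(self):
        assert lrt_pvalue(0.0, 3, "none").p_value == 1.0
        assert lrt_pvalue(0.0, 1, "half_chisq").p_value == 1.0

    def test_half_mixture_single_variance(self):
        res = lrt_pvalue(2.706, df=1, mixture="half_chisq")
        assert res.p_value == pytest.approx(0.05, abs=5e-4)

    def test_mixture_never_exceeds_plain(self):
        for q in (0.5, 1.0, 3.84, 10.0):
            for df in (1, 2, 5):
                assert (lrt_pvalue(q, df, "half_chisq").p_value
                        <= lrt_pvalue(q, df, "none").p_value + 1e-12)

    def test_tiny_negative_clamped(self):
        assert lrt_pvalue(-1e-8, 1).p_value == 1.0
        with pytest.raises(ValueError):
            lrt_pvalue(-0.5, 1)


class TestHierarchy:
    @pytest.mark.parametrize("k,expected", [(5, (5, 10, 10)),
                                            (2, (2, 1, 1))])
    def test_df_counting(self, k, expected, behavior_table):
        from copestyle.data_model import BEHAVIOR_TRAITS
        res = compare_hierarchy(behavior_table, BEHAVIOR_TRAITS[:k],
                                starts=(0.3,))
        assert tuple(res.tests["df"]) == expected
        assert (res.tests["statistic"] >= 0).all()

    def test_univariate_uses_half_mixture(self, balanced_table, plain_trait):
        res = compare_hierarchy(balanced_table, (plain_trait,))
        assert list(res.tests["mixture"]) == ["half_chisq"]
        assert len(res.fits) == 2


class TestCorrFromCov:
    def test_published_among_individual_correlations(self):
        corr = corr_from_cov(BEHAVIOR_I_REFERENCE, warn_out_of_range=False)
        # TL-ACT, TIM-TOR as printed; tolerance reflects rounding of
        # the printed covariance entries
        assert corr[0, 1] == pytest.approx(0.986, abs=1.5e-3)
        assert corr[3, 4] == pytest.approx(0.927, abs=1.5e-3)
        assert corr[1, 4] == pytest.approx(0.992, abs=1.5e-3)

    def test_zero_cov_gives_zero(self):
        corr = corr_from_cov(np.diag([1.0, 2.0]))
        assert corr[0, 1] == 0.0 and corr[0, 0] == 1.0

    def test_non_positive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            corr_from_cov(np.array([[0.0, 0.1], [0.1, 1.0]]))

    def test_out_of_range_flagged_not_truncated(self):
        M = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.warns(UserWarning, match="not PSD"):
            corr = corr_from_cov(M)
        assert corr[0, 1] == pytest.approx(1.2)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        M = np.array([[2.0, 0.8], [0.8, 1.5]])
        D = np.diag([c, 1.0])
        assert corr_from_cov(D @ M @ D)[0, 1] == pytest.approx(
            corr_from_cov(M)[0, 1], rel=1e-9)


class TestRepeatability:
    def test_balanced_example(self, balanced_table, plain_trait):
        fit = reml_fit(balanced_table,
                       ModelSpec(traits=(plain_trait,),
                                 I_structure="diagonal",
                                 R_structure="diagonal"))
        rep, se = repeatability(fit, "y")
        assert rep == pytest.approx(0.75, abs=1e-5)
        assert se > 0

    def test_boundary_gives_zero(self, plain_trait):
        tab = ObservationTable(pd.DataFrame({
            "individual_id": list("AABBCC"), "trial_number": [1, 2] * 3,
            "y": [1.0, 9.0, 2.0, 8.0, 3.0, 7.0]}))
        fit = reml_fit(tab, ModelSpec(traits=(plain_trait,),
                                      I_structure="diagonal",
                                      R_structure="diagonal"))
        rep, _ = repeatability(fit, "y")
        assert rep == 0.0

    def test_requires_individual_component(self, balanced_table, plain_trait):
        fit = reml_fit(balanced_table,
                       ModelSpec(traits=(plain_trait,), I_structure="absent",
                                 R_structure="diagonal"))
        with pytest.raises(ValueError):
            repeatability(fit, "y")

    def test_sd_unit_traits_in_unit_interval(self, behavior_table):
        from copestyle.data_model import BEHAVIOR_TRAITS
        fit = reml_fit(behavior_table,
                       ModelSpec(traits=BEHAVIOR_TRAITS[:2]), starts=(0.3,))
        for t in fit.trait_names:
            rep, _ = repeatability(fit, t)
            assert 0.0 <= rep <= 1.0


class TestBetweenTrial:
    def _table(self, t1, t2):
        rows = []
        for i, (a, b) in enumerate(zip(t1, t2)):
            rows.append({"individual_id": f"i{i}", "trial_number": 1, "h": a})
            rows.append({"individual_id": f"i{i}", "trial_number": 2, "h": b})
        return ObservationTable(pd.DataFrame(rows))

    def test_perfect_anticorrelation(self):
        tab = self._table([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        r, se, sig = between_trial_correlations(tab, "h", covariates=(),
                                                transform="none")
        assert r.loc["T1", "T2"] == pytest.approx(-1.0)

    def test_identical_trials(self):
        tab = self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        r, _, _ = between_trial_correlations(tab, "h", covariates=(),
                                             transform="none")
        assert r.loc["T1", "T2"] == pytest.approx(1.0)

    def test_independent_trials_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        tab = self._table(rng.normal(size=n) + 5, rng.normal(size=n) + 5)
        r, _, _ = between_trial_correlations(tab, "h", covariates=(),
                                             transform="none")
        assert abs(r.loc["T1", "T2"]) < 3 / np.sqrt(n)

    def test_too_few_pairs(self):
        tab = self._table([1.0, 2.0], [2.0, 1.0])
        with pytest.raises(Exception):
            between_trial_correlations(tab, "h", covariates=(),
                                       transform="none")


class TestPairedAndValidation:
    def test_df_convention(self):
        rng = np.random.default_rng(1)
        pre, post = rng.normal(size=99) + 1, rng.normal(size=99)
        res = paired_mean_change(pre, post)
        assert res.df == 98 and res.n_pairs == 99

    def test_equal_samples_t_zero(self):
        res = paired_mean_change([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_example(self):
        res = paired_mean_change([1.0, 2.0, 3.0], [0.0, 2.0, 2.0])
        assert res.statistic == pytest.approx(2.0)
        assert res.df == 2

    def test_missing_pairs_dropped(self):
        res = paired_mean_change([1.0, np.nan, 3.0, 4.0],
                                 [0.0, 2.0, 1.0, np.nan])
        assert res.n_pairs == 2

    def test_validation_perfect_correlations(self):
        w = np.array([10.0, 20.0, 40.0, 80.0])
        m = np.array([1.0, 1.2, 0.9, 1.1])
        r, se, p, n = validation_correlation(w, 3.0 * w, m)
        assert r == pytest.approx(1.0)
        b = np.exp(-np.log(w))       # anti-monotone on the log scale
        r2, *_ = validation_correlation(w, b * m * m, m)
        assert r2 == pytest.approx(-1.0)

    def test_validation_matches_direct_pearson(self):
        w = np.array([12.0, 25.0, 7.0, 40.0])
        b = np.array([30.0, 55.0, 21.0, 70.0])
        m = np.array([1.1, 0.9, 1.3, 1.0])
        r, se, p, n = validation_correlation(w, b, m)
        direct = np.corrcoef(np.log(w / m), np.log(b / m))[0, 1]
        assert r == pytest.approx(direct, abs=1e-12)
        assert se == pytest.approx(np.sqrt((1 - r ** 2) / (n - 2)))
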