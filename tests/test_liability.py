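import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import spearmanr

from copestyle.data_model import DataError, ObservationTable, TraitSpec
from copestyle.liability import (MCMCSettings, fit_binary_liability,
                                 fit_bivariate_binary_gaussian,
                                 liability_icc,
                                 observed_scale_repeatability)

FAST = MCMCSettings(iterations=3000, burnin=500, thin=5)


def _binary_table(n_ind=60, n_obs=6, v_i=1.0, seed=0, mu=0.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(v_i), n_ind)
    rows = []
    for i in range(n_ind):
        for j in range(n_obs):
            lat = mu + u[i] + rng.normal()
            rows.append({"individual_id": f"i{i}", "trial_number": j + 1,
                         "emREF": int(rng.random() < expit(lat))})
    return ObservationTable(pd.DataFrame(rows))


def _bivariate_table(n_ind=150, n_obs=8, r=0.8, seed=0):
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    U = rng.multivariate_normal([0, 0], cov, size=n_ind)
    rows = []
    for i in range(n_ind):
        for j in range(n_obs):
            lat = U[i, 0] + rng.normal()
            rows.append({
                "individual_id": f"i{i}", "trial_number": j + 1,
                "emREF": int(rng.random() < expit(lat)),
                "g": U[i, 1] + rng.normal(),
            })
    return ObservationTable(pd.DataFrame(rows))


GAUSS = TraitSpec(name="g", transform="none", scale_to_sd=False,
                  fixed_effects=("mean",))


class TestICCFormula:
    def test_known_values(self):
        assert liability_icc(0.0, 1.0) == 0.0
        # 1 / (2 + pi^2/3)
        assert liability_icc(1.0, 1.0) == pytest.approx(0.189, abs=5e-4)

    def test_limit_to_one(self):
        assert liability_icc(1e9, 1.0) > 0.999

    def test_monotone_in_v_i(self):
        grid = np.linspace(0, 10, 25)
        vals = liability_icc(grid)
        assert np.all(np.diff(vals) > 0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            liability_icc(-0.1)

    def test_applies_to_chains(self):
        chain = np.array([0.0, 1.0, 4.0])
        out = liability_icc(chain)
        assert out.shape == (3,) and out[0] == 0.0


class TestUnivariate:
    def test_single_class_rejected(self):
        df = pd.DataFrame({"individual_id": list("AABB"),
                           "trial_number": [1, 2, 1, 2],
                           "emREF": [1, 1, 1, 1]})
        with pytest.raises(DataError):
            fit_binary_liability(ObservationTable(df),
                                 fixed_effects=("mean",), settings=FAST)

    def test_deterministic_given_seed(self):
        tab = _binary_table(n_ind=25, n_obs=4)
        a = fit_binary_liability(tab, fixed_effects=("mean",), settings=FAST,
                                 seed=9)
        b = fit_binary_liability(tab, fixed_effects=("mean",), settings=FAST,
                                 seed=9)
        assert np.array_equal(a.chains["V_I"], b.chains["V_I"])
        assert len(a.chains["V_I"]) == FAST.n_retained

    def test_chain_diagnostics_on_well_posed_data(self):
        tab = _binary_table(n_ind=100, n_obs=8, v_i=1.5, seed=4)
        post = fit_binary_liability(tab, fixed_effects=("mean",), seed=1)
        summ = post.summary()
        assert summ.loc["V_I", "rhat"] < 1.1
        assert summ.loc["V_I", "ess"] > 100

    def test_liability_variance_tracks_generating_variance(self):
        # dichotomized-Gaussian grid: estimated latent V_I must be
        # monotone (rank correlation) in the generating variance
        grid = [0.2, 0.6, 1.2, 2.4, 4.8]
        est = []
        for i, v in enumerate(grid):
            tab = _binary_table(n_ind=100, n_obs=8, v_i=v, seed=30 + i)
            post = fit_binary_liability(tab, fixed_effects=("mean",),
                                        settings=FAST, seed=i)
            est.append(np.mean(post.chains["V_I"]))
        rho = spearmanr(grid, est).statistic
        assert rho > 0.9


class TestBivariate:
    def test_recovers_strong_positive_correlation(self):
        tab = _bivariate_table(r=0.8, seed=2)
        post = fit_bivariate_binary_gaussian(
            tab, gaussian_trait=GAUSS, binary_fixed_effects=("mean",),
            settings=FAST, seed=3)
        r_mean = float(np.mean(post.chains["r_I"]))
        assert r_mean == pytest.approx(0.8, abs=0.15)
        lo, hi = post.hpd("r_I")
        assert lo <= hi and -1 <= lo and hi <= 1

    def test_null_correlation_hpd_covers_zero(self):
        tab = _bivariate_table(n_ind=100, n_obs=6, r=0.0, seed=8)
        post = fit_bivariate_binary_gaussian(
            tab, gaussian_trait=GAUSS, binary_fixed_effects=("mean",),
            settings=FAST, seed=5)
        lo, hi = post.hpd("r_I")
        assert lo < 0.0 < hi

    def test_deterministic_given_seed(self):
        tab = _bivariate_table(n_ind=30, n_obs=4, r=0.5, seed=1)
        kw = dict(gaussian_trait=GAUSS, binary_fixed_effects=("mean",),
                  settings=FAST, seed=11)
        a = fit_bivariate_binary_gaussian(tab, **kw)
        b = fit_bivariate_binary_gaussian(tab, **kw)
        assert np.array_equal(a.chains["r_I"], b.chains["r_I"])

    def test_summary_table_layout(self):
        tab = _bivariate_table(n_ind=30, n_obs=4, r=0.5, seed=1)
        post = fit_bivariate_binary_gaussian(
            tab, gaussian_trait=GAUSS, binary_fixed_effects=("mean",),
            settings=FAST, seed=11)
        summ = post.summary()
        assert {"r_I", "V_I_binary", "V_I_gaussian"} <= set(summ.index)
        assert {"mode", "hpd_lower", "hpd_upper"} <= set(summ.columns)


class TestObservedScale:
    def test_warns_and_returns_repeatability(self):
        tab = _binary_table(n_ind=40, n_obs=6, v_i=2.0, seed=6)
        with pytest.warns(UserWarning, match="binary"):
            rep, se, fit = observed_scale_repeatability(
                tab, fixed_effects=("mean",))
        assert 0.0 <= rep <= 1.0 and se >= 0.0
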