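"""Tests of the power module: log-normal round trip, effect sizes,
correlated grouping, and Monte-Carlo power against closed-form oracles.

The regression scheme builds the outcome from the *sample-standardized*
target column, so its exact reference is the noncentral-t power of a
fixed-design slope test with ncp = r*sqrt(n)/sqrt(1-r^2); the Fisher-z
correlation-test power is a close approximation and is checked with a
wider band.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from forestpower.power import (DEFAULT_GRID, EffectSpec, effect_size,
                               effect_sizes, fit_lognormal, group_correlated,
                               power_classification, power_regression,
                               sample_size_recommendation, synthesize)
from forestpower.simdata import ConfigurationError, SimulationConfig, simulate_uniform


from oracles import (fisher_z_power, fixed_design_regression_power,
                     two_sample_t_power)


@pytest.fixture(scope="module")
def mvln_model():
    """A genuinely log-normal 4-variable model (the model's assumption)."""
    rng = np.random.default_rng(42)
    A = rng.standard_normal((4, 4)) * 0.15
    cov = A @ A.T + 0.05 * np.eye(4)
    Z = rng.multivariate_normal(np.zeros(4), cov, size=5000)
    X = pd.DataFrame(np.exp(Z), columns=list("abcd"))
    return fit_lognormal(X)


class TestFitLogNormal:
    def test_positive_data_no_shift(self):
        X = np.abs(np.random.default_rng(0).standard_normal((50, 3))) + 0.1
        m = fit_lognormal(X)
        assert np.all(m.shift == 0)

    def test_negative_minimum_shifted_past_zero(self):
        X = np.random.default_rng(1).uniform(size=(50, 2))
        X[:, 0] -= 2.5  # min below -1.5
        m = fit_lognormal(X)
        assert m.shift[0] > -X[:, 0].min()
        assert m.shift[1] == 0

    def test_constant_variable_flagged(self):
        X = np.column_stack([np.full(30, 2.0),
                             np.random.default_rng(2).uniform(size=30) + 1])
        m = fit_lognormal(pd.DataFrame(X, columns=["const", "var"]))
        assert "const" in m.zero_variance

    def test_too_few_samples(self):
        with pytest.raises(ConfigurationError):
            fit_lognormal(np.ones((2, 2)))


class TestSynthesize:
    def test_determinism(self, mvln_model):
        a = synthesize(mvln_model, 100, seed=5)
        b = synthesize(mvln_model, 100, seed=5)
        assert np.array_equal(a, b)

    def test_identity_covariance_uncorrelated(self):
        from forestpower.power import LogNormalModel
        m = LogNormalModel(mean=np.zeros(3), cov=np.eye(3) * 0.2,
                           shift=np.zeros(3), names=["a", "b", "c"])
        S = synthesize(m, 20000, seed=6)
        c = np.corrcoef(S, rowvar=False)
        assert np.abs(c[np.triu_indices(3, 1)]).max() < 0.03

    def test_perfectly_correlated_pair_round_trips(self):
        rng = np.random.default_rng(7)
        x = np.exp(rng.standard_normal(500) * 0.3)
        X = np.column_stack([x, 2.0 * x])
        S = synthesize(fit_lognormal(X), 20000, seed=8)
        assert np.corrcoef(S, rowvar=False)[0, 1] > 0.999

    def test_round_trip_correlations_within_002(self, mvln_model):
        rng = np.random.default_rng(42)
        A = rng.standard_normal((4, 4)) * 0.15
        cov = A @ A.T + 0.05 * np.eye(4)
        Z = rng.multivariate_normal(np.zeros(4), cov, size=5000)
        X = np.exp(Z)
        S = synthesize(mvln_model, 100_000, seed=9)
        diff = np.abs(np.corrcoef(X, rowvar=False) - np.corrcoef(S, rowvar=False))
        assert diff.max() < 0.02


class TestEffectSize:
    def test_self_correlation(self):
        y = np.random.default_rng(10).standard_normal(40)
        assert effect_size(y, y, "pearson_r").value == pytest.approx(1.0)

    def test_cohens_d_hand_computed(self):
        x = np.array([0, 1, 2, 2, 3, 4], dtype=float)
        g = np.array([0, 0, 0, 1, 1, 1])
        # means 1 and 3, pooled sd 1
        assert effect_size(x, g, "cohens_d").value == pytest.approx(2.0)

    def test_independent_large_n(self):
        rng = np.random.default_rng(11)
        r = effect_size(rng.uniform(size=20000), rng.uniform(size=20000),
                        "pearson_r").value
        assert abs(r) < 0.03

    def test_zero_pooled_sd(self):
        with pytest.raises(ConfigurationError):
            effect_size(np.ones(6), np.array([0, 0, 0, 1, 1, 1]), "cohens_d")


class TestGrouping:
    def test_simulation_groups_recovered(self):
        # six correlated blocks of ten plus one free variable
        ds = simulate_uniform(SimulationConfig(n_obs=200, p_total=61, seed=12))
        eff = effect_sizes(ds.X, ds.y.to_numpy(), "pearson_r")
        groups = group_correlated(ds.X, eff, threshold=0.8)
        multi = [g for g in groups.groups if len(g) > 1]
        single = [g for g in groups.groups if len(g) == 1]
        assert len(multi) == 6 and all(len(g) == 10 for g in multi)
        assert single == [["V61"]]
        for g, rep in zip(groups.groups, groups.representatives):
            assert rep in g
            assert abs(eff[rep].value) == max(abs(eff[v].value) for v in g)

    def test_strict_threshold_all_singletons(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.uniform(size=(100, 6)))
        eff = effect_sizes(X, rng.standard_normal(100), "pearson_r")
        groups = group_correlated(X, eff, threshold=0.999)
        assert all(len(g) == 1 for g in groups.groups)

    def test_identical_pair_representative(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(size=80)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.uniform(size=80)})
        eff = {"a": EffectSpec("a", "pearson_r", 0.2),
               "b": EffectSpec("b", "pearson_r", 0.5),
               "c": EffectSpec("c", "pearson_r", 0.1)}
        groups = group_correlated(X, eff, threshold=0.95)
        assert ["a", "b"] in groups.groups
        assert "b" in groups.representatives  # larger effect wins
        eff["b"] = EffectSpec("b", "pearson_r", 0.2)  # tie -> first in order
        groups = group_correlated(X, eff, threshold=0.95)
        assert "a" in groups.representatives


class TestPowerRegression:
    @pytest.mark.parametrize("r, n", [(0.5, 50), (0.3, 100)])
    def test_matches_fixed_design_oracle(self, mvln_model, r, n):
        pg = power_regression(mvln_model, EffectSpec("c", "pearson_r", r),
                              n_grid=[n], reps=400, seed=15)
        mc = pg.table["power"].iloc[0]
        se = max(pg.table["mc_se"].iloc[0], 1e-3)
        assert abs(mc - fixed_design_regression_power(r, n)) <= 3 * se
        # the Fisher-z approximation sits close by
        assert abs(mc - fisher_z_power(r, n)) <= 0.06

    def test_null_effect_calibrated(self, mvln_model):
        pg = power_regression(mvln_model, EffectSpec("a", "pearson_r", 0.0),
                              n_grid=[40, 200], reps=400, seed=16)
        for p in pg.table["power"]:
            assert abs(p - 0.05) < 0.04

    def test_monotone_in_n(self, mvln_model):
        pg = power_regression(mvln_model, EffectSpec("b", "pearson_r", 0.35),
                              n_grid=[15, 40, 120], reps=300, seed=17)
        pw = pg.table["power"].to_numpy()
        se = pg.table["mc_se"].to_numpy()
        assert pw[1] >= pw[0] - 3 * max(se[0], se[1])
        assert pw[2] >= pw[1] - 3 * max(se[1], se[2])

    def test_estimates_within_unit_interval(self, mvln_model):
        pg = power_regression(mvln_model, EffectSpec("d", "pearson_r", 0.6),
                              n_grid=[10, 30], reps=100, seed=18)
        assert ((pg.table["power"] >= 0) & (pg.table["power"] <= 1)).all()
        assert ((pg.table["fpr"] >= 0) & (pg.table["fpr"] <= 1)).all()


class TestPowerClassification:
    @pytest.mark.parametrize("d, n", [(1.0, 20), (0.5, 30)])
    def test_matches_noncentral_t_oracle(self, mvln_model, d, n):
        pg = power_classification(mvln_model, EffectSpec("c", "cohens_d", d),
                                  n_grid=[n], reps=400, seed=19)
        mc = pg.table["power"].iloc[0]
        se = max(pg.table["mc_se"].iloc[0], 1e-3)
        assert abs(mc - two_sample_t_power(d, n)) <= 3 * se + 0.01

    def test_statsmodels_cross_check(self):
        # independent implementation of the same two-sample power
        from statsmodels.stats.power import TTestIndPower
        ours = two_sample_t_power(1.0, 20)
        theirs = TTestIndPower().power(effect_size=1.0, nobs1=20, ratio=1.0,
                                       alpha=0.05, alternative="two-sided")
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_null_effect_calibrated(self, mvln_model):
        pg = power_classification(mvln_model, EffectSpec("a", "cohens_d", 0.0),
                                  n_grid=[25], reps=400, seed=20)
        assert abs(pg.table["power"].iloc[0] - 0.05) < 0.04

    def test_partners_never_reduce_power(self, mvln_model):
        alone = power_classification(mvln_model, EffectSpec("a", "cohens_d", 0.6),
                                     n_grid=[15], reps=300, seed=21)
        helped = power_classification(mvln_model, EffectSpec("a", "cohens_d", 0.6),
                                      partners=["b"], n_grid=[15], reps=300, seed=21)
        assert helped.table["power"].iloc[0] >= alone.table["power"].iloc[0] - 0.05


class TestRecommendation:
    def _grid(self, ns, powers):
        from forestpower.power import PowerGrid
        return PowerGrid(table=pd.DataFrame(
            {"variable": "v", "effect_type": "pearson_r", "effect": 0.5,
             "n": ns, "power": powers, "tpr": powers, "fpr": 0.05,
             "reps": 100, "mc_se": 0.02}))

    def test_lookup(self):
        assert sample_size_recommendation(
            self._grid([10, 50, 100], [0.2, 0.8, 1.0]), 0.8) == 50

    def test_beyond_grid(self):
        assert sample_size_recommendation(
            self._grid([10, 50], [0.2, 0.9]), 0.99) == "beyond grid"

    def test_invalid_target(self):
        with pytest.raises(ConfigurationError):
            sample_size_recommendation(self._grid([10], [0.5]), 1.5)

    def test_default_grid_strictly_increasing(self):
        assert all(a < b for a, b in zip(DEFAULT_GRID, DEFAULT_GRID[1:]))

    def test_nonmonotone_grid_rejected(self, mvln_model):
        with pytest.raises(ConfigurationError):
            power_regression(mvln_model, EffectSpec("a", "pearson_r", 0.3),
                             n_grid=[20, 20], reps=60, seed=0)
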