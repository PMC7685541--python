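"""Tests of the four selection algorithms: perfect-predictor recovery,
null calibration, p-value arithmetic, elimination trajectory and
determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from forestpower.rf import ForestSpec
from forestpower.selectors import (boruta_select, model_permutation_test,
                                   permutation_select, rfe_select,
                                   rfe_trajectory_sizes)
from forestpower.simdata import ConfigurationError


def _perfect_feature_problem(n=70, p_noise=50, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.standard_normal(n)
    X = pd.DataFrame(rng.uniform(size=(n, p_noise)),
                     columns=[f"N{i}" for i in range(p_noise)])
    X.insert(0, "signal", y)
    return X, y


class TestBoruta:
    def test_perfect_predictor_confirmed(self):
        X, y = _perfect_feature_problem()
        out = boruta_select(X, y, spec=ForestSpec("regression", n_trees=50, seed=1),
                            max_runs=25)
        assert "signal" in out.selected
        assert out.decision["signal"] == "confirmed"

    def test_pure_noise_confirms_almost_nothing(self, noise_data):
        X, y = noise_data
        n_confirmed = []
        for seed in (0, 1):
            out = boruta_select(pd.DataFrame(X), y,
                                spec=ForestSpec("regression", n_trees=50, seed=seed),
                                max_runs=25)
            n_confirmed.append(len(out.selected))
        assert np.mean(n_confirmed) <= 1.5  # alpha*p = 1.5

    def test_invalid_max_runs(self, noise_data):
        X, y = noise_data
        with pytest.raises(ConfigurationError):
            boruta_select(pd.DataFrame(X), y,
                          spec=ForestSpec("regression"), max_runs=0)

    def test_determinism(self):
        X, y = _perfect_feature_problem(n=50, p_noise=15)
        spec = ForestSpec("regression", n_trees=40, seed=9)
        a = boruta_select(X, y, spec=spec, max_runs=10)
        b = boruta_select(X, y, spec=spec, max_runs=10)
        assert a.selected == b.selected
        pd.testing.assert_series_equal(a.decision, b.decision)


class TestPermutationSelect:
    def test_perfect_feature_gets_minimum_p(self):
        X, y = _perfect_feature_problem(n=50, p_noise=8, seed=2)
        out = permutation_select(X, y, spec=ForestSpec("regression", n_trees=40, seed=3),
                                 n_perm=99)
        assert out.p_values["signal"] == pytest.approx(1 / 100)
        assert "signal" in out.selected

    def test_null_pvalues_roughly_uniform(self):
        # pooled p-values across pure-noise runs should pass a KS test
        rng = np.random.default_rng(11)
        pvals = []
        for seed in range(3):
            X = pd.DataFrame(rng.uniform(size=(40, 8)))
            y = rng.standard_normal(40)
            out = permutation_select(X, y, spec=ForestSpec("regression", n_trees=40,
                                                           seed=seed), n_perm=60)
            pvals.extend(out.p_values.tolist())
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_bh_selection_is_subset_of_raw(self):
        ds_X, y = _perfect_feature_problem(n=60, p_noise=12, seed=4)
        raw = permutation_select(ds_X, y, spec=ForestSpec("regression", n_trees=40,
                                                          seed=5), n_perm=40)
        p = raw.diagnostics["raw_p_values"].to_numpy()
        _, p_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert set(np.flatnonzero(p_adj < 0.05)) <= set(np.flatnonzero(p < 0.05))

    def test_unreachable_alpha_warns(self, noise_data):
        X, y = noise_data
        with pytest.warns(UserWarning, match="cannot reach"):
            permutation_select(pd.DataFrame(X[:30, :4]), y[:30],
                               spec=ForestSpec("regression", n_trees=30, seed=0),
                               n_perm=30, alpha=0.01)

    def test_n_perm_floor(self, noise_data):
        X, y = noise_data
        with pytest.raises(ConfigurationError):
            permutation_select(pd.DataFrame(X), y,
                               spec=ForestSpec("regression"), n_perm=19)

    def test_determinism(self):
        X, y = _perfect_feature_problem(n=40, p_noise=6, seed=6)
        spec = ForestSpec("regression", n_trees=30, seed=7)
        a = permutation_select(X, y, spec=spec, n_perm=25)
        b = permutation_select(X, y, spec=spec, n_perm=25)
        pd.testing.assert_series_equal(a.p_values, b.p_values)


class TestModelPermutationTest:
    def test_strong_signal_minimum_p(self):
        X, y = _perfect_feature_problem(n=60, p_noise=4, seed=8)
        p = model_permutation_test(X, y, spec=ForestSpec("regression", n_trees=40,
                                                         seed=9), n_perm=24)
        assert p == pytest.approx(1 / 25)

    def test_null_p_not_extreme(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.uniform(size=(40, 5)))
        y = rng.standard_normal(40)
        p = model_permutation_test(X, y, spec=ForestSpec("regression", n_trees=30,
                                                         seed=14), n_perm=24)
        assert p > 0.05


class TestRFE:
    def test_trajectory_sizes_closed_form(self):
        # ceil drop arithmetic: 100 -> 80 -> 64 -> 51 -> ...
        assert rfe_trajectory_sizes(100, 0.2)[:4] == [100, 80, 64, 51]

    @given(st.integers(2, 400), st.floats(0.05, 0.8))
    @settings(max_examples=80, deadline=None)
    def test_trajectory_property(self, p, frac):
        sizes = rfe_trajectory_sizes(p, frac)
        assert sizes[0] == p and sizes[-1] == 1
        for a, b in zip(sizes, sizes[1:]):
            assert b == max(a - int(np.ceil(frac * a)), 1)

    def test_perfect_feature_survives(self):
        X, y = _perfect_feature_problem(n=60, p_noise=20, seed=10)
        out = rfe_select(X, y, spec=ForestSpec("regression", n_trees=60, seed=11))
        assert "signal" in out.selected

    def test_se_rule_zero_picks_minimum(self):
        X, y = _perfect_feature_problem(n=50, p_noise=10, seed=12)
        out = rfe_select(X, y, spec=ForestSpec("regression", n_trees=50, seed=13),
                         se_rule=0.0)
        d = out.diagnostics
        assert d["threshold"] == pytest.approx(d["min_loss"])
        assert len(out.selected) >= 1  # always returns at least one variable

    def test_invalid_drop_fraction(self, noise_data):
        X, y = noise_data
        with pytest.raises(ConfigurationError):
            rfe_select(pd.DataFrame(X), y, spec=ForestSpec("regression"),
                       drop_fraction=1.2)

    def test_determinism(self):
        X, y = _perfect_feature_problem(n=50, p_noise=12, seed=14)
        spec = ForestSpec("regression", n_trees=40, seed=15)
        a = rfe_select(X, y, spec=spec)
        b = rfe_select(X, y, spec=spec)
        assert a.selected == b.selected
        assert a.diagnostics["losses"] == b.diagnostics["losses"]


class TestTypeIControl:
    def test_noise_selection_rate_bounded(self):
        """On pure noise, Boruta and the permutation selector keep the
        expected selected-set size at or below alpha * p."""
        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.uniform(size=(50, 40)))
        y = rng.standard_normal(50)
        b = boruta_select(X, y, spec=ForestSpec("regression", n_trees=50, seed=21),
                          max_runs=25)
        pr = permutation_select(X, y, spec=ForestSpec("regression", n_trees=50,
                                                      seed=22), n_perm=40)
        assert len(b.selected) <= 4        # alpha*p = 2, MC slack
        assert len(pr.selected) <= 6
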