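"""Unit and property tests for the greedy MDL regression core."""

import numpy as np
import pytest
from sklearn.base import clone

from cher.l0 import (
    CherModel,
    L0ContextRegressor,
    data_bits,
    greedy_fit,
    predict,
    refit_model,
    uniform_costs,
)

from _oracles import exhaustive_dl_search


class TestDataBits:
    def test_halving_rss_at_n32_saves_16_bits(self):
        assert data_bits(8.0, 32) - data_bits(16.0, 32) == pytest.approx(-16.0, abs=1e-12)

    def test_rss_equal_n_codes_zero_bits(self):
        assert data_bits(32.0, 32) == pytest.approx(0.0, abs=1e-12)

    def test_zero_rss_hits_epsilon_floor_not_minus_inf(self):
        out = data_bits(0.0, 10)
        assert np.isfinite(out) and out == data_bits(1e-30, 10)

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            data_bits(1.0, 0)
        with pytest.raises(ValueError):
            data_bits(1.0, 5, df=0)

    def test_df_correction_penalizes_smaller_residual_dof(self):
        # same rss looks worse (longer code) when more coefficients were spent
        assert data_bits(10.0, 20, df=15) > data_bits(10.0, 20, df=19)


class TestUniformCosts:
    @pytest.mark.parametrize("p,expected", [(8, 5.0), (1, 2.0), (1024, 12.0)])
    def test_feature_cost_is_log2p_plus_2(self, p, expected):
        cm = uniform_costs(p, 0)
        assert np.allclose(cm.feature_cost, expected, atol=1e-12)

    @pytest.mark.parametrize("T,expected", [(2, 1.0), (1, 0.0), (4, 2.0)])
    def test_split_cost_is_log2T(self, T, expected):
        cm = uniform_costs(4, T)
        assert np.allclose(cm.split_cost, expected, atol=1e-12)

    def test_zero_features_rejected(self):
        with pytest.raises(ValueError):
            uniform_costs(0, 1)


class TestGreedyFit:
    def test_recovers_single_shared_predictor(self, single_predictor_data):
        X, y, Z = single_predictor_data
        costs = uniform_costs(7, 1)
        m = greedy_fit(X, y, Z, costs)
        assert set(m.beta_shared) == {0}
        assert not m.beta_arm1 and not m.beta_arm0 and m.split is None
        # exhaustive search over the same model class agrees
        dl_o, s_o = exhaustive_dl_search(X, y, Z, costs.feature_cost, costs.split_cost, max_k=2)
        assert s_o == (None, frozenset({0}), frozenset(), frozenset())
        assert m.dl_total >= dl_o - 1e-9

    def test_constant_phenotype_gives_empty_model(self):
        X = np.random.default_rng(0).standard_normal((30, 5))
        y = np.full(30, 2.5)
        m = greedy_fit(X, y)
        assert m.selected_features() == {}
        assert m.intercept == pytest.approx(2.5)
        assert np.isfinite(m.dl_total)

    def test_contextual_signal_placed_in_correct_arm(self, rng):
        n = 80
        X = rng.standard_normal((n, 5))
        Z = np.zeros((n, 1))
        Z[rng.permutation(n)[: n // 2], 0] = 1.0
        y = np.where(Z[:, 0] == 1, 4.0 * X[:, 0], 0.0) + 0.1 * rng.standard_normal(n)
        costs = uniform_costs(5, 1)
        m = greedy_fit(X, y, Z, costs)
        assert m.split == 0
        assert set(m.beta_arm1) == {0} and not m.beta_shared
        dl_o, s_o = exhaustive_dl_search(X, y, Z, costs.feature_cost, costs.split_cost, max_k=2)
        assert s_o[0] == 0 and s_o[2] == frozenset({0})

    def test_dl_strictly_decreases_along_path(self, single_predictor_data):
        X, y, Z = single_predictor_data
        m = greedy_fit(X, y, Z)
        path = np.asarray(m.dl_path, dtype=float)
        assert np.all(np.diff(path) < 0)
        assert m.dl_total <= path[0]

    def test_permutation_invariance(self, single_predictor_data, rng):
        X, y, Z = single_predictor_data
        perm = rng.permutation(len(y))
        m1 = greedy_fit(X, y, Z)
        m2 = greedy_fit(X[perm], y[perm], Z[perm])
        assert m1.beta_shared == pytest.approx(m2.beta_shared)
        assert m1.split == m2.split
        assert m1.dl_total == pytest.approx(m2.dl_total)

    def test_doubling_costs_never_grows_selection(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((50, 10))
            y = 2 * X[:, 0] - 1.5 * X[:, 3] + r.standard_normal(50)
            base = uniform_costs(10, 0)
            dbl = uniform_costs(10, 0)
            dbl.feature_cost = base.feature_cost * 2
            sel_base = set(greedy_fit(X, y, None, base).selected_features())
            sel_dbl = set(greedy_fit(X, y, None, dbl).selected_features())
            assert sel_dbl <= sel_base

    def test_missing_values_rejected(self):
        X = np.ones((10, 2))
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(ValueError):
            greedy_fit(X, y)

    def test_weighted_fit_matches_ols_on_expanded_resample(self, rng):
        n, p = 40, 4
        X = rng.standard_normal((n, p))
        y = 5.0 * X[:, 1] + 0.3 * rng.standard_normal(n)
        idx = rng.integers(0, n, n)
        uniq, mult = np.unique(idx, return_counts=True)
        m = greedy_fit(X[uniq], y[uniq], None, uniform_costs(p, 0),
                       sample_weight=mult, standardize=False)
        assert set(m.beta_shared) == {1}
        # coefficient must equal the plain OLS fit on the duplicated rows
        A = np.column_stack([np.ones(n), X[idx, 1]])
        beta = np.linalg.lstsq(A, y[idx], rcond=None)[0]
        assert m.intercept == pytest.approx(beta[0], abs=1e-8)
        assert m.beta_shared[1] == pytest.approx(beta[1], abs=1e-8)


class TestPredict:
    def test_empty_model_predicts_intercept(self):
        m = CherModel(split=None, beta_shared={}, beta_arm1={}, beta_arm0={},
                      intercept=1.5, intercept_arm_offset=0.0, dl_total=0.0,
                      rss=0.0, n_used=10)
        out = predict(m, np.zeros((4, 3)))
        assert np.allclose(out, 1.5)

    def test_arm1_only_model_changes_predictions_only_where_z1(self):
        m = CherModel(split=0, beta_shared={}, beta_arm1={1: 2.0}, beta_arm0={},
                      intercept=0.0, intercept_arm_offset=0.0, dl_total=0.0,
                      rss=0.0, n_used=10)
        X = np.ones((6, 3))
        Z = np.array([[1], [0], [1], [0], [1], [0]], dtype=float)
        out = predict(m, X, Z)
        assert np.allclose(out[Z[:, 0] == 1], 2.0)
        assert np.allclose(out[Z[:, 0] == 0], 0.0)

    def test_round_trip_rss_matches_model(self, single_predictor_data):
        X, y, Z = single_predictor_data
        m = greedy_fit(X, y, Z)
        yhat = predict(m, X, Z)
        assert float(((y - yhat) ** 2).sum()) == pytest.approx(m.rss, rel=1e-9)

    def test_missing_split_column_rejected(self):
        m = CherModel(split=2, beta_shared={}, beta_arm1={0: 1.0}, beta_arm0={},
                      intercept=0.0, intercept_arm_offset=0.0, dl_total=0.0,
                      rss=0.0, n_used=10)
        with pytest.raises(ValueError):
            predict(m, np.zeros((3, 2)), np.zeros((3, 1)))


class TestRefitModel:
    def test_contextual_roles_require_split(self):
        X = np.random.default_rng(1).standard_normal((20, 3))
        with pytest.raises(ValueError):
            refit_model(X, X[:, 0], None, [], [1], [], None)

    def test_refit_reproduces_greedy_coefficients(self, single_predictor_data):
        X, y, Z = single_predictor_data
        m = greedy_fit(X, y, Z)
        r = refit_model(X, y, Z, sorted(m.beta_shared), sorted(m.beta_arm1),
                        sorted(m.beta_arm0), m.split)
        assert r.beta_shared == pytest.approx(m.beta_shared)
        assert r.rss == pytest.approx(m.rss, rel=1e-9)


class TestEstimator:
    def test_fit_predict_and_clone(self, single_predictor_data):
        X, y, Z = single_predictor_data
        est = L0ContextRegressor()
        est.fit(X, y, Z)
        assert est.model_.beta_shared
        assert est.predict(X, Z).shape == y.shape
        clone(est)  # sklearn param contract

    def test_score_is_r2_like(self, single_predictor_data):
        X, y, Z = single_predictor_data
        est = L0ContextRegressor().fit(X, y, Z)
        yhat = est.predict(X, Z)
        assert 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum() > 0.95
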