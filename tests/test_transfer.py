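"""Tests for similarity weights, the prior update and cost conversion."""

import numpy as np
import pytest

from cher.l0 import uniform_costs
from cher.transfer import (
    BootstrapSummary,
    phenotype_similarity,
    priors_to_costs,
    update_priors,
)


def make_summary(tau, split_freq=None, K=None):
    tau = np.asarray(tau, dtype=float)
    K = tau.shape[1] if K is None else K
    sf = np.zeros((0, K)) if split_freq is None else np.asarray(split_freq, dtype=float)
    z = np.zeros_like(tau)
    return BootstrapSummary(tau=tau, freq_shared=tau.copy(), freq_arm1=z,
                            freq_arm0=z.copy(), split_freq=sf, B=25,
                            B_eff=np.full(K, 25))


class TestPhenotypeSimilarity:
    def test_uncentred_sigmoid_midpoint_and_extreme(self, rng):
        y0 = rng.standard_normal(100)
        Y = np.column_stack([y0, rng.standard_normal(100)])
        W = phenotype_similarity(Y, sigmoid_scale=5.0, center=0.0)
        # perfectly correlated with itself -> sigmoid(5) on the diagonal
        assert W[0, 0] == pytest.approx(1 / (1 + np.exp(-5)), abs=1e-12)
        Yp = np.column_stack([y0, y0])  # r = 1 off-diagonal
        Wp = phenotype_similarity(Yp, sigmoid_scale=5.0, center=0.0)
        assert Wp[0, 1] == pytest.approx(1 / (1 + np.exp(-5)), abs=1e-12)

    def test_correlation_at_centre_gives_half_weight(self, rng):
        a = rng.standard_normal(4000)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(4000)  # r ~ 0.5
        W = phenotype_similarity(np.column_stack([a, b]), sigmoid_scale=8.0, center=0.5)
        assert W[0, 1] == pytest.approx(0.5, abs=0.05)

    def test_symmetry(self, rng):
        Y = rng.standard_normal((50, 6))
        W = phenotype_similarity(Y)
        assert np.allclose(W, W.T)

    def test_too_few_complete_pairs_fall_back_with_warning(self):
        Y = np.full((10, 2), np.nan)
        Y[:, 0] = np.arange(10.0)
        Y[:2, 1] = [1.0, 2.0]  # only 2 complete pairs
        with pytest.warns(UserWarning):
            W = phenotype_similarity(Y, sigmoid_scale=5.0, center=0.0)
        assert W[0, 1] == pytest.approx(0.5)

    def test_single_phenotype_rejected(self):
        with pytest.raises(ValueError):
            phenotype_similarity(np.ones((5, 1)))


class TestUpdatePriors:
    def test_single_neighbour_weighted_average(self):
        # one neighbour with w = 1, tau = 0.3, a = b = 0.5 -> 8/15
        bs = make_summary([[0.3, 0.0]])
        W = np.ones((2, 2))
        ps = update_priors(bs, W, 0.5, 0.5)
        assert ps.P[0, 1] == pytest.approx((0.3 + 0.5) / 1.5, abs=1e-12)

    def test_unanimous_neighbour_gives_certain_prior(self):
        bs = make_summary([[1.0, 0.0]])
        ps = update_priors(bs, np.ones((2, 2)), 0.5, 0.5)
        assert ps.P[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_neighbour_weight_degenerates_to_half(self):
        bs = make_summary([[1.0, 0.0]])
        with pytest.warns(UserWarning):
            ps = update_priors(bs, np.zeros((2, 2)))
        assert np.allclose(ps.P, 0.5)
        assert np.allclose(ps.baseline, 0.5)

    def test_beta_posterior_denominator_variant(self):
        bs = make_summary([[0.3, 0.0]])
        ps = update_priors(bs, np.ones((2, 2)), denominator="beta_posterior")
        assert ps.P[0, 1] == pytest.approx(0.8 / 2.0, abs=1e-12)

    def test_baseline_is_no_evidence_prior(self):
        bs = make_summary([[0.0, 0.0]])
        ps = update_priors(bs, np.ones((2, 2)))
        assert ps.baseline[0] == pytest.approx(0.5 / 1.5)
        assert ps.P[0, 0] == pytest.approx(ps.baseline[0])

    def test_monotone_in_tau(self, rng):
        K, p = 4, 6
        W = phenotype_similarity(rng.standard_normal((80, K)))
        tau = rng.random((p, K))
        ps = update_priors(make_summary(tau), W)
        tau2 = tau.copy()
        tau2[2, 1] = min(1.0, tau2[2, 1] + 0.3)
        ps2 = update_priors(make_summary(tau2), W)
        assert np.all(ps2.P[2] >= ps.P[2] - 1e-12)
        others = np.arange(p) != 2
        assert np.allclose(ps2.P[others], ps.P[others])

    def test_pull_toward_common_tau_strengthens_with_weight(self):
        # constant tau* across neighbours: |P - tau*| shrinks as total weight grows
        tau_star = 0.7
        gaps = []
        for w in (0.2, 1.0, 5.0, 25.0):
            bs = make_summary([[tau_star, 0.0]])
            W = np.full((2, 2), w)
            ps = update_priors(bs, W)
            gaps.append(abs(ps.P[0, 1] - tau_star))
        assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))


class TestPriorsToCosts:
    def _state(self, P, baseline, split_P=None, T=0):
        from cher.transfer import PriorState
        P = np.asarray(P, dtype=float).reshape(-1, 1)
        sp = (np.asarray(split_P, dtype=float).reshape(-1, 1)
              if split_P is not None else np.zeros((T, 1)))
        return PriorState(P=P, split_P=sp, baseline=np.array([baseline]),
                          a=0.5, b=0.5, W=np.ones((1, 1)), sigmoid_scale=8.0)

    def test_unanchored_matches_direct_coding(self):
        # P = 1/p -> uniform cost; P = 1 -> coefficient bits; P = 0.5, p=1024 -> 3
        ps = self._state([1 / 1024, 1.0, 0.5], baseline=0.1)
        cm = priors_to_costs(ps, 1024, 0, 0, anchored=False)
        assert cm.feature_cost[0] == pytest.approx(np.log2(1024) + 2, abs=1e-12)
        assert cm.feature_cost[1] == pytest.approx(2.0, abs=1e-12)
        assert cm.feature_cost[2] == pytest.approx(3.0, abs=1e-12)

    def test_anchored_endpoints(self):
        base = 0.5 / 11.5
        ps = self._state([base, 1.0, 0.2], baseline=base)
        cm = priors_to_costs(ps, 100, 0, 0)
        assert cm.feature_cost[0] == pytest.approx(np.log2(100) + 2, abs=1e-9)
        assert cm.feature_cost[1] == pytest.approx(2.0, abs=1e-9)
        assert 2.0 < cm.feature_cost[2] < np.log2(100) + 2

    def test_degenerate_baseline_gives_uniform(self):
        ps = self._state([0.5, 0.9], baseline=1.0)
        cm = priors_to_costs(ps, 50, 0, 0)
        assert np.allclose(cm.feature_cost, np.log2(50) + 2)

    @pytest.mark.parametrize("anchored", [True, False])
    def test_cap_and_floor_properties(self, rng, anchored):
        base = 0.04
        P = np.clip(rng.random(30), base, 1.0)
        ps = self._state(P, baseline=base, split_P=np.clip(rng.random(3), base, 1), T=3)
        cm = priors_to_costs(ps, 30, 3, 0, anchored=anchored)
        uni = uniform_costs(30, 3)
        assert np.all(cm.feature_cost <= uni.feature_cost + 1e-9)
        assert np.all(cm.feature_cost >= cm.coef_bits - 1e-9)
        assert np.all(cm.split_cost <= uni.split_cost + 1e-9)
        assert np.all(cm.split_cost >= 0)

    @pytest.mark.parametrize("anchored", [True, False])
    def test_costs_monotone_decreasing_in_prior(self, anchored):
        base = 0.05
        P = np.linspace(base, 1.0, 20)
        ps = self._state(P, baseline=base)
        cm = priors_to_costs(ps, 20, 0, 0, anchored=anchored)
        assert np.all(np.diff(cm.feature_cost) <= 1e-12)
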