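"""Pair IBD HMM: emissions, level weights, delta estimation and EM."""

import numpy as np
import pytest

from kinhmm.counts import PairWindowData
from kinhmm.emissions import EmissionParams, betabinom_logpmf, delta_constraint_interval
from kinhmm.kin_hmm import (
    em_fit,
    g_weights,
    maximize_delta,
    model_levels,
    window_log_emissions,
)
from kinhmm.models import model_registry
from kinhmm.roh import uniform_roh_prior


@pytest.fixture(scope="module")
def registry():
    return model_registry()


@pytest.fixture()
def params():
    p = EmissionParams(0.2)
    for i in (0, 1, 2, 4):
        lo, _ = delta_constraint_interval(p, i)
        p.delta[i] = max(400.0, lo)
    return p


def _data(D, N):
    return PairWindowData(("i", "j"), np.asarray(D, float), np.asarray(N, float))


class TestWindowEmissions:
    def test_degenerate_mixture_equals_level_pmf(self, registry, params):
        data = _data([3, 1, 0], [20, 10, 0])
        h = uniform_roh_prior(3)
        log_e = window_log_emissions(data, h, registry["unrelated"], params)
        ref = betabinom_logpmf(data.D, data.N, 0.2, params.delta[0])
        np.testing.assert_allclose(log_e[:, 0], ref)

    def test_ibd0_row_independent_of_roh(self, registry, params):
        data = _data([3, 1], [20, 10])
        h1 = np.array([[1.0, 0, 0], [0, 0.4, 0.6]])
        h2 = np.array([[0.2, 0.3, 0.5], [1.0, 0, 0]])
        m = registry["unrelated"]
        np.testing.assert_allclose(
            window_log_emissions(data, h1, m, params),
            window_log_emissions(data, h2, m, params),
        )

    def test_empty_window_emits_one(self, registry, params):
        data = _data([0.0], [0.0])
        log_e = window_log_emissions(data, uniform_roh_prior(1), registry["siblings"], params)
        np.testing.assert_allclose(log_e, 0.0)

    def test_mixture_is_probability_space(self, registry, params):
        data = _data([2.0], [30.0])
        h = np.array([[0.5, 0.3, 0.2]])
        log_e = window_log_emissions(data, h, registry["identical"], params)
        # identical: Z=2 row has levels (2, 4, 4)
        terms = [
            0.5 * np.exp(betabinom_logpmf(2.0, 30.0, params.p[2], params.delta[2])),
            0.3 * np.exp(betabinom_logpmf(2.0, 30.0, params.p[4], params.delta[4])),
            0.2 * np.exp(betabinom_logpmf(2.0, 30.0, params.p[4], params.delta[4])),
        ]
        assert log_e[0, 0] == pytest.approx(np.log(sum(terms)))


class TestGWeights:
    @pytest.mark.parametrize(
        "gamma, h, expected",
        [
            ((0.2, 0.5, 0.3), (1, 0, 0), (0.2, 0.5, 0.3, 0, 0)),
            ((0.2, 0.5, 0.3), (0, 0, 1), (0.2, 0, 0, 0, 0.8)),
            ((1.0, 0.0, 0.0), (0.3, 0.4, 0.3), (1, 0, 0, 0, 0)),
        ],
    )
    def test_level_collapse_examples(self, gamma, h, expected):
        g = g_weights(np.array([gamma]), np.array([h]))
        np.testing.assert_allclose(g[0], expected, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        gamma = rng.dirichlet(np.ones(3), size=50)
        h = rng.dirichlet(np.ones(3), size=50)
        g = g_weights(gamma, h)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(g[:, 3] == 0)


class TestMaximizeDelta:
    def test_parameter_recovery(self, pair_data_sim):
        # delta=50 data; grid-search oracle agrees with the bounded optimizer
        data = pair_data_sim(L=500, N=1000, p=0.2, delta=50.0, seed=3)
        g = np.ones(500)
        est = maximize_delta(data, g, 0.2, (1e-6, 1e6), prev=500.0)
        assert 35.0 <= est <= 70.0
        grid = np.linspace(20, 120, 600)
        costs = [
            float(betabinom_logpmf(data.D, data.N, 0.2, d).sum()) for d in grid
        ]
        assert est == pytest.approx(grid[int(np.argmax(costs))], abs=5.0)

    def test_optimality_certificate_single_window(self):
        data = _data([4.0], [20.0])
        g = np.ones(1)
        lo, hi = 10.0, 1e4

        def cost(d):
            return float(betabinom_logpmf(4.0, 20.0, 0.3, d))

        est = maximize_delta(data, g, 0.3, (lo, hi), prev=100.0)
        assert cost(est) >= cost(lo) - 1e-9
        assert cost(est) >= cost(hi) - 1e-9

    def test_data_at_mean_drives_delta_to_upper_bound(self):
        # rate exactly p: variance collapses toward binomial
        data = _data([20.0] * 4, [100.0] * 4)
        est = maximize_delta(data, np.ones(4), 0.2, (1.0, 1e6), prev=10.0)
        assert est > 1e5

    def test_zero_weights_keep_previous(self):
        data = _data([1.0], [10.0])
        assert maximize_delta(data, np.zeros(1), 0.2, (1.0, 1e6), prev=123.0) == 123.0


class TestEMFit:
    def test_single_state_model_direct_loglik(self, registry):
        data = _data([2, 3, 1, 0], [20, 25, 15, 10])
        h = uniform_roh_prior(4)
        params = EmissionParams(0.2)
        fit = em_fit(data, h, registry["unrelated"], params, seed=0)
        direct = betabinom_logpmf(data.D, data.N, 0.2, fit.delta_hat[0]).sum()
        assert fit.loglik == pytest.approx(direct)
        assert fit.converged

    def test_loglik_monotone_within_tolerance(self, registry, pair_data_sim):
        data = pair_data_sim(L=60, N=200, p=0.15, delta=80.0, seed=9)
        h = uniform_roh_prior(60)
        fit = em_fit(data, h, registry["siblings"], EmissionParams(0.2), seed=4)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs > -1e-6)

    def test_same_seed_identical_output(self, registry, pair_data_sim):
        data = pair_data_sim(L=40, N=100, p=0.15, delta=60.0, seed=2)
        h = uniform_roh_prior(40)
        f1 = em_fit(data, h, registry["third_degree"], EmissionParams(0.2), seed=11)
        f2 = em_fit(data, h, registry["third_degree"], EmissionParams(0.2), seed=11)
        assert f1.loglik == f2.loglik
        np.testing.assert_array_equal(f1.viterbi_path, f2.viterbi_path)
        assert f1.delta_hat == f2.delta_hat

    def test_gamma_rows_and_path_states(self, registry, pair_data_sim):
        data = pair_data_sim(L=50, N=150, p=0.1, delta=100.0, seed=5)
        h = uniform_roh_prior(50)
        for label in ("grandparent_grandchild", "siblings", "parent_child"):
            fit = em_fit(data, h, registry[label], EmissionParams(0.2), seed=3)
            np.testing.assert_allclose(fit.gamma.sum(axis=1), 1.0, atol=1e-9)
            assert set(np.unique(fit.viterbi_path)) <= set(registry[label].states)

    def test_levels_follow_model_states(self, registry):
        assert model_levels(registry["unrelated"]) == (0,)
        assert model_levels(registry["parent_child"]) == (1, 2, 4)
        assert model_levels(registry["identical"]) == (2, 4)
        assert model_levels(registry["siblings"]) == (0, 1, 2, 4)
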