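import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gamma as gamma_fn

from conftest import random_pattern
from fractrl.fracdyn import (
    FractionalNetwork,
    expansion_matrices,
    is_controllable_numeric,
    numeric_rank,
    psi_weights,
    reachability_matrix,
    sample_realization,
    simulate,
)
from fractrl.netio import DirectedPattern


def gamma_ratio_psi(alpha: float, j: int) -> float:
    """Independent oracle: direct Gamma evaluation of the kernel."""
    return gamma_fn(j - alpha) / (gamma_fn(-alpha) * gamma_fn(j + 1))


class TestPsiWeights:
    def test_half_order_values(self):
        # frozen from the Gamma-function oracle at alpha = 0.5
        assert psi_weights(0.5, 2).psi == pytest.approx([1.0, -0.5, -0.125])

    def test_integer_alpha_truncates(self):
        assert psi_weights(1, 4).psi == pytest.approx([1, -1, 0, 0, 0])

    @pytest.mark.parametrize("alpha", [-0.3, 0.0, 0.5, 1.0, 2.7])
    def test_zeroth_weight_is_one(self, alpha):
        assert psi_weights(alpha, 0).psi == pytest.approx([1.0])

    def test_negative_horizon_errors(self):
        with pytest.raises(ValueError):
            psi_weights(0.5, -1)

    @pytest.mark.parametrize("alpha", np.arange(0.1, 1.0, 0.1).round(1).tolist())
    def test_recurrence_matches_gamma_formula(self, alpha):
        rec = psi_weights(alpha, 50).psi
        direct = np.array([gamma_ratio_psi(alpha, j) for j in range(51)])
        np.testing.assert_allclose(rec, direct, rtol=1e-10)

    @given(st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=25, deadline=None)
    def test_fractional_weights_negative_after_zero(self, alpha):
        psi = psi_weights(alpha, 30).psi
        assert psi[0] == 1.0
        assert np.all(psi[1:] < 0)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_partial_sums_positive_and_decaying(self, alpha):
        psi = psi_weights(alpha, 5000).psi
        partial = np.cumsum(psi)
        assert np.all(partial > 0)
        assert partial[-1] < partial[100] < partial[10]

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_loglog_slope_is_power_law(self, alpha):
        psi = psi_weights(alpha, 10**4).psi
        j = np.arange(100, 10**4 + 1)
        slope = np.polyfit(np.log(j), np.log(np.abs(psi[j])), 1)[0]
        assert abs(slope - (-(1 + alpha))) < 0.05

    def test_no_overflow_large_horizon(self):
        psi = psi_weights(0.5, 10**6).psi
        assert np.all(np.isfinite(psi))


def _fixed_net(pattern, alpha, rng):
    return sample_realization(pattern, rng, alpha=np.full(pattern.n_nodes, alpha))


class TestExpansionMatrices:
    def test_markov_limit_alpha_one(self):
        rng = np.random.default_rng(0)
        pat = random_pattern(rng, 4, density=0.4)
        net = _fixed_net(pat, 1.0, rng)
        mats = expansion_matrices(net, 3)
        np.testing.assert_allclose(mats.A_seq[0], net.weights + np.eye(4))
        for A_j in mats.A_seq[1:]:
            np.testing.assert_allclose(A_j, 0.0)

    def test_half_order_lag_one_diagonal(self):
        rng = np.random.default_rng(1)
        pat = random_pattern(rng, 3, density=0.4)
        net = _fixed_net(pat, 0.5, rng)
        mats = expansion_matrices(net, 2)
        np.testing.assert_allclose(mats.A_seq[1], 0.125 * np.eye(3))

    def test_scalar_sequence(self):
        pat = DirectedPattern(1, set())
        net = FractionalNetwork(pat, alpha=[0.5], weights=np.zeros((1, 1)))
        mats = expansion_matrices(net, 2)
        vals = [float(A[0, 0]) for A in mats.A_seq]
        assert vals == pytest.approx([0.5, 0.125, 0.0625])

    def test_missing_weights_errors(self):
        net = FractionalNetwork(DirectedPattern(2, {(0, 1)}), alpha=[0.5, 0.5])
        with pytest.raises(ValueError, match="sample_realization"):
            expansion_matrices(net, 2)


class TestSimulate:
    def test_zero_everything_stays_zero(self):
        rng = np.random.default_rng(2)
        pat = random_pattern(rng, 4, density=0.5)
        net = _fixed_net(pat, 0.5, rng)
        traj = simulate(net, [0], None, np.zeros((5, 1)), np.zeros(4), 5)
        np.testing.assert_allclose(traj.states, 0.0)

    def test_alpha_one_equals_lti_loop(self):
        rng = np.random.default_rng(3)
        pat = random_pattern(rng, 5, density=0.4)
        net = _fixed_net(pat, 1.0, rng)
        K = 12
        driven = [0, 2]
        inputs = rng.standard_normal((K, 2))
        x0 = rng.standard_normal(5)
        traj = simulate(net, driven, None, inputs, x0, K)
        # independent oracle: direct x[k+1] = (A + I) x[k] + B u[k]
        B = np.zeros((5, 2))
        B[0, 0] = B[2, 1] = 1.0
        x = x0.copy()
        for k in range(K):
            x = (net.weights + np.eye(5)) @ x + B @ inputs[k]
            np.testing.assert_allclose(traj.states[k + 1], x, atol=1e-12)

    def test_scalar_memory_example(self):
        pat = DirectedPattern(1, set())
        net = FractionalNetwork(pat, alpha=[0.5], weights=np.zeros((1, 1)))
        traj = simulate(net, [], None, np.zeros((2, 0)), np.ones(1), 2)
        assert traj.states[1, 0] == pytest.approx(0.5)
        assert traj.states[2, 0] == pytest.approx(0.375)

    def test_superposition(self):
        rng = np.random.default_rng(4)
        pat = random_pattern(rng, 4, density=0.5)
        net = _fixed_net(pat, 0.4, rng)
        K, driven = 8, [1, 3]
        u1, u2 = rng.standard_normal((2, K, 2))
        x1, x2 = rng.standard_normal((2, 4))
        a, b = 0.7, -1.3
        sa = simulate(net, driven, None, u1, x1, K).states
        sb = simulate(net, driven, None, u2, x2, K).states
        sc = simulate(net, driven, None, a * u1 + b * u2, a * x1 + b * x2, K).states
        np.testing.assert_allclose(sc, a * sa + b * sb, atol=1e-10)

    def test_truncation_tail_is_small(self):
        rng = np.random.default_rng(5)
        pat = random_pattern(rng, 3, density=0.4)
        net = _fixed_net(pat, 0.6, rng)
        # scale weights down for a stable comparison of long horizons
        net.weights *= 0.2
        x0 = rng.standard_normal(3)
        full = simulate(net, [], None, np.zeros((40, 0)), x0, 40).states
        trunc = simulate(net, [], None, np.zeros((40, 0)), x0, 40, truncation=30).states
        rel_err = np.max(np.abs(full - trunc)) / np.max(np.abs(full))
        assert rel_err < 1e-2
        np.testing.assert_allclose(full[:31], trunc[:31], atol=1e-14)

    def test_dimension_mismatch_errors(self):
        rng = np.random.default_rng(6)
        pat = random_pattern(rng, 3, density=0.5)
        net = _fixed_net(pat, 0.5, rng)
        with pytest.raises(ValueError):
            simulate(net, [0], None, np.zeros((4, 2)), np.zeros(3), 4)
        with pytest.raises(ValueError):
            simulate(net, [0], None, np.zeros((4, 1)), np.zeros(2), 4)


class TestReachabilityMatrix:
    def test_t1_is_input_matrix(self):
        rng = np.random.default_rng(7)
        pat = random_pattern(rng, 4, density=0.5)
        net = _fixed_net(pat, 0.5, rng)
        R = reachability_matrix(net, [1, 3], 1, b_gains=[2.0, 3.0])
        expected = np.zeros((4, 2))
        expected[1, 0], expected[3, 1] = 2.0, 3.0
        np.testing.assert_allclose(R, expected)

    def test_alpha_one_matches_kalman_column_space(self):
        rng = np.random.default_rng(8)
        pat = random_pattern(rng, 5, density=0.4)
        net = _fixed_net(pat, 1.0, rng)
        driven, T = [0, 2], 4
        R = reachability_matrix(net, driven, T)
        A1 = net.weights + np.eye(5)
        B = np.zeros((5, 2))
        B[0, 0] = B[2, 1] = 1.0
        kalman = np.hstack([np.linalg.matrix_power(A1, k) @ B for k in range(T)])
        assert numeric_rank(R) == numeric_rank(kalman)
        assert numeric_rank(np.hstack([R, kalman])) == numeric_rank(kalman)

    def test_path_graph_full_rank(self):
        rng = np.random.default_rng(9)
        pat = DirectedPattern(3, {(0, 1), (1, 2)})
        net = sample_realization(pat, rng)
        R = reachability_matrix(net, [0], 3)
        assert numeric_rank(R) == 3

    def test_rank_monotone_in_T_and_driven(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            pat = random_pattern(rng, 5, density=0.3)
            net = sample_realization(pat, rng)
            ranks = [numeric_rank(reachability_matrix(net, [0, 1], T)) for T in range(1, 6)]
            assert ranks == sorted(ranks)
            r_small = numeric_rank(reachability_matrix(net, [0], 3))
            r_big = numeric_rank(reachability_matrix(net, [0, 1, 2], 3))
            assert r_small <= r_big

    def test_t_zero_errors(self):
        rng = np.random.default_rng(11)
        net = sample_realization(random_pattern(rng, 3, 0.5), rng)
        with pytest.raises(ValueError):
            reachability_matrix(net, [0], 0)


class TestIsControllableNumeric:
    def test_all_nodes_one_step(self):
        rng = np.random.default_rng(12)
        pat = random_pattern(rng, 5, density=0.3)
        assert is_controllable_numeric(pat, range(5), 1, seed=1)

    def test_empty_driven_false(self):
        pat = DirectedPattern(3, {(0, 1)})
        assert not is_controllable_numeric(pat, [], 3, seed=1)

    def test_star_fractional_vs_integer(self, star3):
        # fractional alpha: distinct memory diagonals act as generic
        # self-loops and the hub alone controls the star in 3 steps
        assert is_controllable_numeric(star3, [0], 3, seed=2)
        # alpha = 1 exactly: repeated unit self-loop weights, rank stalls at 2
        rng = np.random.default_rng(3)
        net = sample_realization(star3, rng, alpha=np.ones(3))
        assert not is_controllable_numeric(net, [0], 3)
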