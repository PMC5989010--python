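"""Network construction, threshold quantiles and conductance moments."""

import numpy as np
import pytest
from scipy.signal import lfilter
from scipy.special import ndtri

import netlr
from netlr.network_model import (CouplingSpec, IntrinsicParams,
                                 SynapseKinetics, build_network,
                                 conductance_moments, effective_parameters,
                                 sample_thresholds)

# hand-built fixtures legitimately leave some cells without input
pytestmark = pytest.mark.filterwarnings("ignore:.*zero in-degree.*")


class TestSampleThresholds:
    def test_lognormal_parameters_forced_by_moment_constraints(self):
        # mean 1 and variance e^{cv^2}-1 pin the underlying normal to
        # location -cv^2/2 = -0.02 and scale cv = 0.2
        th = sample_thresholds(19, 0.2, 0.05, 0.95)
        p = 0.05 + 0.90 * np.arange(19) / 18
        expected = np.exp(-0.02 + 0.2 * ndtri(p))
        np.testing.assert_allclose(th, expected, rtol=1e-12)

    def test_single_threshold_is_the_median(self):
        np.testing.assert_allclose(sample_thresholds(1, 0.2),
                                   [np.exp(-0.02)], rtol=1e-12)

    def test_zero_cv_collapses_to_one(self):
        assert np.all(sample_thresholds(5, 0.0) == 1.0)

    def test_deterministic_and_monotone(self):
        a = sample_thresholds(40, 0.2)
        b = sample_thresholds(40, 0.2)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a) > 0)

    @pytest.mark.parametrize("lo,hi", [(0.0, 0.9), (0.1, 1.0), (0.9, 0.1)])
    def test_invalid_probability_bounds_raise(self, lo, hi):
        with pytest.raises(ValueError):
            sample_thresholds(5, 0.2, lo, hi)


class TestBuildNetwork:
    def test_empty_coupling_gives_empty_adjacency(self):
        coup = CouplingSpec(W=np.zeros((2, 2)), p_conn=np.zeros((2, 2)))
        net = build_network(4, 2, coupling=coup, seed=0,
                            degree_model="bernoulli")
        assert not net.adjacency.any()
        assert not net.in_degree.any()

    def test_bernoulli_in_degree_matches_binomial_expectation(self):
        nets = [build_network(80, 20, seed=s, degree_model="bernoulli")
                for s in range(5)]
        mean_ie = np.mean([n.in_degree[n.e_mask, 1].mean() for n in nets])
        assert abs(mean_ie - 0.35 * 20) < 1.0    # expectation 7

    def test_fixed_in_degree_is_exact(self):
        net = build_network(80, 20, seed=3)
        assert np.all(net.in_degree[net.e_mask, 0] == 32)   # 0.40 * 80
        assert np.all(net.in_degree[net.e_mask, 1] == 7)    # 0.35 * 20
        assert np.all(net.in_degree[net.i_mask, 0] == 16)   # 0.20 * 80
        assert np.all(net.in_degree[net.i_mask, 1] == 8)    # 0.40 * 20

    def test_no_self_connections_and_reproducible(self):
        for model in ("fixed_in", "bernoulli"):
            a = build_network(10, 5, seed=11, degree_model=model)
            b = build_network(10, 5, seed=11, degree_model=model)
            assert not np.diag(a.adjacency).any()
            np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_preset_carries_table_weights(self):
        cfg = netlr.preset_config("asynchronous")
        net = netlr.network_from_config(cfg)
        W = net.coupling.W
        assert (W[0, 1], W[1, 0], W[0, 0], W[1, 1]) == (10.0, 5.0, 0.5, 5.0)

    def test_zero_in_degree_with_nonzero_weight_warns(self):
        coup = CouplingSpec.from_named(W_EE=1.0, W_EI=1.0, W_IE=1.0,
                                       W_II=1.0, p_EE=0.0, p_EI=0.0,
                                       p_IE=0.0, p_II=0.0)
        with pytest.warns(UserWarning, match="zero in-degree"):
            build_network(2, 2, coupling=coup, seed=0)


def _two_cell_net(alpha_E=1.0, tau_r_E=1.0, tau_d_E=5.0, W_EE=1.0):
    """Cell 1 receives exactly one E synapse from cell 0."""
    kin = SynapseKinetics(alpha_E=alpha_E, tau_r_E=tau_r_E, tau_d_E=tau_d_E)
    coup = CouplingSpec.from_named(W_EE=W_EE, W_EI=1, W_IE=1, W_II=1,
                                   p_EE=0, p_EI=0, p_IE=0, p_II=0)
    net = build_network(2, 1, synapses=kin, coupling=coup, seed=0)
    net.adjacency[:] = False
    net.adjacency[1, 0] = True
    net.in_degree[:] = 0
    net.in_degree[1, 0] = 1
    return net


class TestConductanceMoments:
    def test_zero_rates_give_zero_moments(self, asyn_network):
        m = conductance_moments(asyn_network, np.zeros(100))
        assert not m.mean_g.any() and not m.var_g.any()

    def test_single_synapse_example(self):
        # alpha_hat = 1, nu = 0.01/ms, tau_r = 1, tau_d = 5:
        # mean = 0.01, var = 0.5 * 0.01 * (1/6)
        net = _two_cell_net()
        m = conductance_moments(net, np.array([0.01, 0.0, 0.0]))
        assert m.alpha_hat[1, 0] == 1.0
        np.testing.assert_allclose(m.mean_g[1, 0], 0.01, rtol=1e-12)
        np.testing.assert_allclose(m.var_g[1, 0], 0.01 / 12, rtol=1e-12)

    def test_var_mean_ratio_is_rate_independent(self, asyn_network):
        rng = np.random.default_rng(0)
        m = conductance_moments(asyn_network, rng.uniform(0.001, 0.05, 100))
        kin = asyn_network.synapses
        for X in (0, 1):
            ratio = kin.tau_r[X] / (kin.tau_r[X] + kin.tau_d[X])
            drive = m.mean_g[:, X] > 0
            np.testing.assert_allclose(
                (m.var_g[:, X] / m.mean_g[:, X])[drive],
                (0.5 * m.alpha_hat[:, X] * ratio)[drive], rtol=1e-12)

    def test_mean_invariant_to_in_degree_variance_scales_inverse(self):
        # same raw weight, same uniform presynaptic rate, different N_in
        rate = 0.02
        means, variances, n_ins = [], [], (4, 16)
        for n_in in n_ins:
            net = build_network(n_in + 1, 1, seed=0, coupling=CouplingSpec(
                W=np.ones((2, 2)), p_conn=np.zeros((2, 2))))
            net.adjacency[:] = False
            net.adjacency[0, 1:n_in + 1] = True
            net.in_degree[:] = 0
            net.in_degree[0, 0] = n_in
            m = conductance_moments(
                net, np.full(net.n_cells, rate))
            means.append(m.mean_g[0, 0])
            variances.append(m.var_g[0, 0])
        np.testing.assert_allclose(means[0], means[1], rtol=1e-12)
        np.testing.assert_allclose(variances[0] / variances[1],
                                   n_ins[1] / n_ins[0], rtol=1e-12)

    def test_negative_rates_rejected(self, asyn_network):
        with pytest.raises(ValueError, match="nonnegative"):
            conductance_moments(asyn_network, np.full(100, -1.0))

    def test_poisson_driven_synapse_matches_shot_noise_formulas(self):
        # independent oracle: discretized Poisson impulses through the exact
        # cascade of two first-order filters (IIR via lfilter)
        tau_r, tau_d, alpha_hat, nu = 1.0, 5.0, 1.0, 0.01
        dt, n = 0.01, 20_000_000         # 200 s
        rng = np.random.default_rng(42)
        counts = rng.poisson(nu * dt, size=n).astype(float)
        # forward Euler of the filter cascade: each spike jumps g1 by
        # alpha_hat; g relaxes toward g1 with time constant tau_d
        g1 = lfilter([1.0], [1, -(1 - dt / tau_r)], alpha_hat * counts)
        g = lfilter([dt / tau_d], [1, -(1 - dt / tau_d)], g1)
        burn = int(100 / dt)
        g = g[burn:]
        mean_expected = alpha_hat * nu * tau_r
        var_expected = 0.5 * alpha_hat**2 * nu * tau_r * tau_r / (tau_r + tau_d)
        assert abs(g.mean() - mean_expected) / mean_expected < 0.05
        assert abs(g.var() - var_expected) / var_expected < 0.05


class TestEffectiveParameters:
    def test_uncoupled_limit(self, asyn_network):
        m = conductance_moments(asyn_network, np.zeros(100))
        cells = effective_parameters(asyn_network, m)
        assert np.all(cells.g0 == 1.0)
        assert np.all(cells.E_rev == 0.0)

    def test_caption_level_values(self):
        # <g_E> = 0.0053, <g_I> = 1.83 with the standard reversals
        g0 = 1 + 0.0053 + 1.83
        E_rev = (0.0053 * 6.5 - 1.83 * 0.5) / g0
        assert abs(g0 - 2.8353) < 1e-12
        net = _two_cell_net()
        m = conductance_moments(net, np.zeros(3))
        m.mean_g[0] = [0.0053, 1.83]
        cells = effective_parameters(net, m)
        np.testing.assert_allclose(cells.E_rev[0], E_rev, rtol=1e-12)
        np.testing.assert_allclose(cells.E_rev[0], -0.3106, atol=5e-5)

    def test_reversal_approaches_excitatory_limit(self):
        net = _two_cell_net()
        m = conductance_moments(net, np.zeros(3))
        m.mean_g[0] = [1e6, 1.83]
        cells = effective_parameters(net, m)
        assert abs(cells.E_rev[0] - net.intrinsic.E_E) < 1e-4

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            IntrinsicParams(E_I=0.5)     # E_I must lie below reset
        with pytest.raises(ValueError):
            SynapseKinetics(tau_r_E=0.0)
        with pytest.raises(ValueError):
            CouplingSpec(W=-np.ones((2, 2)), p_conn=np.zeros((2, 2)))
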