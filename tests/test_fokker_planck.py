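"""Threshold-integration engine: rates, susceptibilities, spectra."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erf

from netlr import fokker_planck as fp
from netlr.network_model import EffectiveCell

from conftest import simulate_effective_cell


def make_cell(**kw):
    base = dict(g0=2.5, E_rev=-0.2, sigma_gE2=0.003, sigma_gI2=0.3,
                sigma=1.41, theta=1.0, tau_m=20.0, tau_ref=2.0)
    base.update(kw)
    return EffectiveCell(**base)


class TestSteadyRate:
    def test_noise_free_suprathreshold_period(self):
        # E_rev = 2 > theta: deterministic period tau_m/g0 * ln(E_rev /
        # (E_rev - theta)) plus the refractory time
        cell = make_cell(g0=2.0, E_rev=2.0, sigma_gE2=0.0, sigma_gI2=0.0,
                         sigma=1e-3)
        expected = 1.0 / (10.0 * np.log(2.0) + 2.0)
        nu = fp.steady_rate(cell)
        assert abs(nu[0] - expected) / expected < 0.01

    def test_subthreshold_small_noise_rate_vanishes(self):
        cell = make_cell(g0=1.5, E_rev=0.5, sigma_gE2=0.0, sigma_gI2=0.0,
                         sigma=1e-3)
        assert fp.steady_rate(cell)[0] < 1e-10

    def test_additive_noise_matches_first_passage_quadrature(self):
        # classical OU mean-first-passage integral as independent oracle
        g0, E_rev, sigma, theta, tau_m, tau_ref = 1.5, 0.3, 1.2, 1.0, 20.0, 2.0
        cell = make_cell(g0=g0, E_rev=E_rev, sigma=sigma, theta=theta,
                         sigma_gE2=0.0, sigma_gI2=0.0)
        sv = sigma / np.sqrt(2 * g0)
        xr = (0.0 - E_rev) / (np.sqrt(2) * sv)
        xt = (theta - E_rev) / (np.sqrt(2) * sv)
        T = (tau_m / g0) * np.sqrt(np.pi) * quad(
            lambda x: np.exp(x**2) * (1 + erf(x)), xr, xt)[0]
        oracle = 1.0 / (T + tau_ref)
        nu = fp.steady_rate(cell, fp.VoltageGrid(n_points=2048))
        assert abs(nu[0] - oracle) / oracle < 0.005

    def test_rate_monotone_decreasing_in_threshold(self):
        thetas = np.linspace(0.7, 1.4, 8)
        cell = make_cell(theta=thetas, g0=np.full(8, 2.5),
                         E_rev=np.full(8, -0.2), sigma_gE2=np.full(8, 0.003),
                         sigma_gI2=np.full(8, 0.3), sigma=np.full(8, 1.41))
        nu = fp.steady_rate(cell)
        assert np.all(np.diff(nu) < 0)

    def test_refinement_stability(self):
        cell = make_cell()
        a = fp.steady_rate(cell, fp.VoltageGrid(v_min=-4.0, n_points=1024))
        b = fp.steady_rate(cell, fp.VoltageGrid(v_min=-4.0, n_points=2048))
        assert abs(a[0] - b[0]) / b[0] < 1e-3

    def test_zero_diffusion_everywhere_rejected(self):
        cell = make_cell(sigma=0.0, sigma_gE2=0.0, sigma_gI2=0.0)
        with pytest.raises(fp.ThresholdIntegrationError):
            fp.steady_rate(cell)

    def test_monte_carlo_agreement(self):
        # Euler-Maruyama runs of the effective diffusion, 5 random cells
        rng = np.random.default_rng(7)
        for k in range(5):
            cell = make_cell(g0=rng.uniform(1.5, 3.0),
                             E_rev=rng.uniform(-0.35, 0.1),
                             sigma_gI2=rng.uniform(0.1, 0.5),
                             sigma=rng.uniform(1.2, 2.0),
                             theta=rng.uniform(0.85, 1.15))
            spikes = simulate_effective_cell(cell, duration=15_000.0,
                                             dt=0.005, n_replicas=24,
                                             seed=100 + k)
            mc = np.mean([s.size for s in spikes]) / 15_000.0
            nu = fp.steady_rate(cell)[0]
            assert abs(mc - nu) / nu < 0.03, (k, mc, nu)


class TestSusceptibility:
    @staticmethod
    def _fd(cell, channel, h):
        """Central finite difference of the rate in the channel parameter.

        The mean-conductance channels shift (g_E, g_I), which are recovered
        from (g0, E_rev) by solving the two defining equations.
        """
        def shifted(d):
            if channel in ("mean_gE", "mean_gI"):
                A = np.array([[1.0, 1.0], [cell.E_E, cell.E_I]])
                b = np.array([cell.g0[0] - 1, cell.E_rev[0] * cell.g0[0]])
                gE, gI = np.linalg.solve(A, b)
                if channel == "mean_gE":
                    gE += d
                else:
                    gI += d
                g0 = 1 + gE + gI
                return dataclasses.replace(
                    cell, g0=np.array([g0]),
                    E_rev=np.array([(gE * cell.E_E + gI * cell.E_I) / g0]))
            kw = {"sigma_gE2": cell.sigma_gE2 + d} if channel == "var_gE" \
                else {"sigma_gI2": cell.sigma_gI2 + d}
            return dataclasses.replace(cell, **kw)
        grid = fp.VoltageGrid(v_min=-5.0)
        up = fp.steady_rate(shifted(h), grid)[0]
        dn = fp.steady_rate(shifted(-h), grid)[0]
        return (up - dn) / (2 * h)

    def test_zero_frequency_equals_rate_derivative(self):
        # panel of 10 random cells, all four channels, < 1 % relative
        rng = np.random.default_rng(3)
        grid = fp.VoltageGrid(v_min=-5.0)
        for _ in range(10):
            cell = make_cell(g0=rng.uniform(1.5, 3.2),
                             E_rev=rng.uniform(-0.35, 0.05),
                             sigma_gE2=rng.uniform(0.0, 0.01),
                             sigma_gI2=rng.uniform(0.05, 0.5),
                             sigma=rng.uniform(1.0, 2.2),
                             theta=rng.uniform(0.8, 1.3))
            for ch in fp.CHANNELS:
                an = fp.susceptibility_zero(cell, ch, grid)[0]
                fd = self._fd(cell, ch, 1e-4)
                assert abs(an - fd) / abs(fd) < 0.01, (ch, an, fd)

    def test_spectral_solver_limits_to_zero_frequency_value(self):
        cell = make_cell()
        for ch in fp.CHANNELS:
            A = fp.susceptibility(cell, ch, np.array([0.0, 1e-3]))
            assert abs(A[0, 1] - A[0, 0]) / abs(A[0, 0]) < 0.01
            assert abs(A[0, 0].imag) < 1e-12

    def test_sign_structure(self):
        cell = make_cell()
        assert fp.susceptibility_zero(cell, "mean_gE")[0] > 0
        assert fp.susceptibility_zero(cell, "mean_gI")[0] < 0

    def test_high_frequency_rolloff(self):
        cell = make_cell()
        A = fp.susceptibility(cell, "mean_gE", np.array([0.0, 10.0]))
        assert abs(A[0, 1]) < 0.1 * abs(A[0, 0])

    def test_near_silent_cell_has_negligible_gain(self):
        cell = make_cell(g0=1.2, E_rev=-0.3, sigma=0.35, sigma_gE2=0.0,
                         sigma_gI2=0.0, theta=1.3)
        nu = fp.steady_rate(cell)[0]
        assert nu < 1e-8
        A = fp.susceptibility(cell, "mean_gE", np.array([0.1, 1.0]))
        assert np.all(np.abs(A) < 1e-6)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            fp.susceptibility(make_cell(), "mean_gX", np.array([0.0]))


class TestPowerSpectrum:
    def test_zero_rate_cell_has_zero_spectrum(self):
        cell = make_cell(g0=1.2, E_rev=-0.3, sigma=0.3, sigma_gE2=0.0,
                         sigma_gI2=0.0, theta=1.4)
        C = fp.power_spectrum_uncoupled(cell, fp.default_frequency_grid())
        assert np.all(C == 0.0)

    def test_poisson_like_regime_is_flat_at_rate(self):
        # high noise, low rate: renewal spectrum within 15 % of nu
        cell = make_cell(g0=1.3, E_rev=-0.25, sigma=1.6, sigma_gE2=0.0,
                         sigma_gI2=0.0, theta=1.6)
        nu = fp.steady_rate(cell)[0]
        assert nu * 1e3 < 12.0           # a low-rate cell
        C = fp.power_spectrum_uncoupled(cell, fp.default_frequency_grid())
        assert np.all(np.abs(C[0] - nu) / nu < 0.15)

    def test_high_frequency_limit_is_the_rate(self):
        cell = make_cell()
        nu = fp.steady_rate(cell)[0]
        C = fp.power_spectrum_uncoupled(cell, np.array([50.0]))
        assert abs(C[0, 0] - nu) / nu < 0.02

    def test_zero_frequency_consistent_with_small_omega_limit(self):
        cell = make_cell()
        C = fp.power_spectrum_uncoupled(cell, np.array([0.0, 1e-3]))
        assert abs(C[0, 1] - C[0, 0]) / C[0, 0] < 0.01

    def test_isi_moments_against_ou_quadrature(self):
        # exact first-passage moments of the additive-noise cell via the
        # classical single and double quadrature formulas
        g0, E_rev, sigma, theta, tau_m = 1.5, 0.3, 1.2, 1.0, 20.0
        cell = make_cell(g0=g0, E_rev=E_rev, sigma=sigma, theta=theta,
                         sigma_gE2=0.0, sigma_gI2=0.0)
        tau = tau_m / g0
        sv = sigma / np.sqrt(2 * g0)
        a = (0.0 - E_rev) / (np.sqrt(2) * sv)
        b = (theta - E_rev) / (np.sqrt(2) * sv)
        T1 = tau * np.sqrt(np.pi) * quad(
            lambda x: np.exp(x**2) * (1 + erf(x)), a, b)[0]
        inner = lambda x: quad(
            lambda y: np.exp(y**2) * (1 + erf(y))**2, -8.0, x)[0]
        VarT = 2 * tau**2 * np.pi * quad(
            lambda x: np.exp(x**2) * inner(x), a, b)[0]
        m_th, v_th = fp.isi_moments(cell, fp.VoltageGrid(v_min=-6.0,
                                                         n_points=2048))
        assert abs(m_th[0] - (T1 + cell.tau_ref)) / (T1 + cell.tau_ref) < 0.005
        assert abs(v_th[0] - VarT) / VarT < 0.005

    def test_isi_moments_against_monte_carlo(self):
        cell = make_cell()
        mean_th, var_th = fp.isi_moments(cell)
        spikes = simulate_effective_cell(cell, duration=20_000.0, dt=0.005,
                                         n_replicas=20, seed=5)
        isis = np.concatenate([np.diff(s) for s in spikes if s.size > 1])
        assert abs(isis.mean() - mean_th[0]) / mean_th[0] < 0.03
        assert abs(isis.var() - var_th[0]) / var_th[0] < 0.10

    def test_spectrum_against_monte_carlo_periodogram(self):
        # binned spike trains of the effective diffusion; average
        # periodogram over replicas and compare at moderate frequencies
        cell = make_cell()
        duration, binw = 4000.0, 0.25
        spikes = simulate_effective_cell(cell, duration=duration, dt=0.005,
                                         n_replicas=60, seed=9)
        nbin = int(duration / binw)
        psd = np.zeros(nbin // 2 + 1)
        for s in spikes:
            counts = np.histogram(s, bins=nbin, range=(0, duration))[0]
            y = counts - counts.mean()
            psd += np.abs(np.fft.rfft(y))**2 / duration
        psd /= len(spikes)
        freqs = np.fft.rfftfreq(nbin, d=binw) * 2 * np.pi   # rad/ms
        for w in (0.5, 1.0, 2.0):
            k = np.argmin(np.abs(freqs - w))
            band = slice(max(k - 5, 1), k + 6)
            mc = psd[band].mean()
            th = fp.power_spectrum_uncoupled(cell, freqs[band])[0].mean()
            assert abs(mc - th) / th < 0.15, (w, mc, th)
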