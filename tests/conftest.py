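"""Shared fixtures: solved preset networks and a reference Euler simulator
for the effective single-cell diffusion."""

import numpy as np
import pytest
from numba import njit

import netlr
from netlr.network_model import EffectiveCell


@pytest.fixture(scope="session")
def asyn_network():
    return netlr.network_from_config(netlr.preset_config("asynchronous"),
                                     seed=1)


@pytest.fixture(scope="session")
def asyn_solution(asyn_network):
    sol = netlr.solve_network_rates(asyn_network)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def strong_network():
    return netlr.network_from_config(
        netlr.preset_config("strong_asynchronous"), seed=1)


@pytest.fixture(scope="session")
def strong_solution(strong_network):
    sol = netlr.solve_network_rates(strong_network)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def mini_asyn():
    fx = netlr.make_fixture("mini_asyn")
    sol = netlr.solve_network_rates(fx.network)
    assert sol.converged
    return fx.network, sol


@njit(cache=False)
def _effective_cell_kernel(n_steps, dt, g0, E_rev, sgE, sgI, sigma, theta,
                           E_E, E_I, tau_m, tau_ref, v_reset, n_replicas,
                           seed, theta_eff):
    np.random.seed(seed)
    v = np.zeros(n_replicas)
    ref_left = np.zeros(n_replicas)
    sqdt = np.sqrt(dt)
    cap = int(n_steps * dt * n_replicas) + 1000
    out_t = np.empty(cap)
    out_r = np.empty(cap, dtype=np.int64)
    n_spk = 0
    amp_bg = sigma * np.sqrt(tau_m)
    for k in range(n_steps):
        t = k * dt
        for r in range(n_replicas):
            if ref_left[r] > 0.0:
                ref_left[r] -= dt
                v[r] = v_reset
                continue
            noise = (amp_bg * np.random.normal()
                     + sgE * (v[r] - E_E) * np.random.normal()
                     + sgI * (v[r] - E_I) * np.random.normal()) / tau_m
            v[r] += -g0 * (v[r] - E_rev) / tau_m * dt + noise * sqdt
            if v[r] >= theta_eff:
                if n_spk < cap:
                    out_t[n_spk] = t
                    out_r[n_spk] = r
                    n_spk += 1
                v[r] = v_reset
                ref_left[r] = tau_ref
    return out_t[:n_spk], out_r[:n_spk]


def simulate_effective_cell(cell: EffectiveCell, duration: float,
                            dt: float = 0.005, n_replicas: int = 1,
                            seed: int = 0, continuity_correction: bool = True):
    """Euler-Maruyama reference simulation of the effective diffusion.

    Independent replicas of the same cell run in parallel; returns a list
    of spike-time arrays, one per replica.  Ito convention: multiplicative
    terms use the pre-step voltage.  With ``continuity_correction`` the
    detection threshold is lowered by zeta(1/2)/sqrt(2 pi) * sigma_loc *
    sqrt(dt) — the standard continuity correction for discretely monitored
    first passage, which removes the leading O(sqrt(dt)) rate bias.
    """
    g0 = float(cell.g0[0])
    E_rev = float(cell.E_rev[0])
    sgE = float(np.sqrt(cell.sigma_gE2[0]))
    sgI = float(np.sqrt(cell.sigma_gI2[0]))
    sigma = float(cell.sigma[0])
    theta = float(cell.theta[0])
    theta_eff = theta
    if continuity_correction:
        var_loc = (sigma**2 * cell.tau_m
                   + cell.sigma_gE2[0] * (theta - cell.E_E) ** 2
                   + cell.sigma_gI2[0] * (theta - cell.E_I) ** 2) / cell.tau_m**2
        theta_eff = theta - 0.5826 * np.sqrt(var_loc) * np.sqrt(dt)
    n_steps = int(round(duration / dt))
    out_t, out_r = _effective_cell_kernel(
        n_steps, dt, g0, E_rev, sgE, sgI, sigma, theta,
        cell.E_E, cell.E_I, cell.tau_m, cell.tau_ref, cell.v_reset,
        n_replicas, seed & 0x7FFFFFFF, theta_eff)
    return [out_t[out_r == r] for r in range(n_replicas)]
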