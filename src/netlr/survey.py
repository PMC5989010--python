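"""Parameter sweeps over families of networks.

Surveys vary the recurrent excitatory strengths (W_EE, W_IE) and the
background-noise pair (sigma_E, sigma_I) around a base configuration,
re-solving the self-consistent rates, the zero-frequency correlation
structure and the reduced susceptibility surface for every family member.
One connectivity realization is shared across the grid by default, so that
differences between rows reflect parameters rather than graph resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fokker_planck as fp
from .linear_response import network_correlations
from .network_model import Network, network_from_config, preset_config
from .self_consistency import population_summary, solve_network_rates
from .surface_analysis import (PathSpec, default_axes, motif_regression,
                               path_profile, rate_surface)

__all__ = ["SweepSpec", "SweepRow", "run_sweep", "sweep_preset",
           "shat_f_slope", "analyze_network"]


@dataclass
class SweepSpec:
    """Grid specification for a network-family survey."""

    W_EE_values: list
    W_IE_values: list
    sigma_pairs: list              # list of (sigma_E, sigma_I)
    base_config: dict
    resample_connectivity: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (len(self.W_EE_values) and len(self.W_IE_values)
                and len(self.sigma_pairs)):
            raise ValueError("sweep value lists must be nonempty")
        if min(self.W_EE_values) < 0 or min(self.W_IE_values) < 0:
            raise ValueError("weights must be nonnegative")


@dataclass
class SweepRow:
    """Outputs of the full pipeline for one family member."""

    W_EE: float
    W_IE: float
    sigma_E: float
    sigma_I: float
    converged: bool
    error: str | None
    spectral_radius: float = np.nan
    rate_E_hz: float = np.nan
    rate_I_hz: float = np.nan
    mean_gI: float = np.nan
    E_rev: float = np.nan
    mean_EE_corr: float = np.nan
    r2_by_order: dict = field(default_factory=dict)
    r2_by_type: dict = field(default_factory=dict)
    shat_curve: dict | None = None
    shat_slope_low: float = np.nan
    shat_slope_full: float = np.nan


def shat_f_slope(curve: dict, low_half: bool = True) -> float:
    """Fitted slope of S_hat against F along a path profile.

    With ``low_half`` only samples at F below the curve's median positive
    rate enter the fit (the low-rate branch).
    """
    F, S = np.asarray(curve["F"]), np.asarray(curve["S_hat"])
    ok = np.isfinite(F) & np.isfinite(S) & (F > 0)
    if low_half:
        ok &= F <= np.median(F[ok])
    if ok.sum() < 3:
        return np.nan
    return float(np.polyfit(F[ok], S[ok], 1)[0])


def analyze_network(network: Network, k_max: int = 4,
                    grid: fp.VoltageGrid | None = None,
                    surface_n: int = 41) -> SweepRow:
    """Run the full single-network pipeline and condense it into a row."""
    W = network.coupling.W
    row = SweepRow(W_EE=float(W[0, 0]), W_IE=float(W[1, 0]),
                   sigma_E=float(network.intrinsic.sigma_E),
                   sigma_I=float(network.intrinsic.sigma_I),
                   converged=False, error=None)
    sol = solve_network_rates(network, grid=grid)
    row.converged = bool(sol.converged)
    if not sol.converged:
        row.error = f"rate solver did not converge (residual {sol.residual:.2e})"
        return row
    summ = population_summary(network, sol)
    row.rate_E_hz = summ.rate * 1e3
    row.rate_I_hz = float(np.mean(sol.rates[network.i_mask])) * 1e3
    row.mean_gI = summ.mean_gI
    row.E_rev = summ.E_rev
    corr = network_correlations(network, sol, k_max=k_max, grid=grid)
    row.spectral_radius = corr.spectral_radius
    table = corr.pair_table(network, pairs="EE")
    row.mean_EE_corr = float(np.mean(table["rho"]))
    row.r2_by_order = motif_regression(
        table["rho"], {k: table[f"R{k}"] for k in range(1, k_max + 1)})
    row.r2_by_type = motif_regression(
        table["R2"], {lab: table[lab] for lab in
                      ("I_common", "E_common", "chain_correlating",
                       "chain_decorrelating")})
    gI_axis, theta_axis = default_axes(summ, n=surface_n)
    p = network.intrinsic
    surf = rate_surface(gI_axis, theta_axis, summ,
                        intrinsic_tau_m=p.tau_m, tau_ref=p.tau_ref,
                        v_reset=p.v_reset, E_E=p.E_E, E_I=p.E_I, grid=grid)
    # the network's own trajectory through the plane: theta varies across
    # cells while g_I stays near its mean (a "horizontal" path)
    curve = path_profile(surf, PathSpec(family="horizontal",
                                        anchor=(summ.mean_gI, 1.0)))
    row.shat_curve = {"F": curve["F"], "S_hat": curve["S_hat"],
                      "theta": curve["theta"]}
    row.shat_slope_low = shat_f_slope(row.shat_curve)
    row.shat_slope_full = shat_f_slope(row.shat_curve, low_half=False)
    return row


def run_sweep(spec: SweepSpec, k_max: int = 4,
              grid: fp.VoltageGrid | None = None,
              surface_n: int = 41) -> pd.DataFrame:
    """Execute the sweep; one row per (sigma pair, W_EE, W_IE).

    Per-row failures are recorded in the ``error`` column and never abort
    the sweep.  Deterministic for a fixed spec (shared connectivity seed,
    or per-row seeds derived from it when resampling is requested).
    """
    base = network_from_config(spec.base_config, seed=spec.seed)
    rows = []
    idx = 0
    for sE, sI in spec.sigma_pairs:
        for W_EE in spec.W_EE_values:
            for W_IE in spec.W_IE_values:
                idx += 1
                if spec.resample_connectivity:
                    net = network_from_config(spec.base_config,
                                              seed=spec.seed + idx)
                else:
                    net = base
                net = replace(net, intrinsic=replace(
                    net.intrinsic, sigma_E=float(sE), sigma_I=float(sI)))
                net = net.with_weights(W_EE=float(W_EE), W_IE=float(W_IE))
                try:
                    row = analyze_network(net, k_max=k_max, grid=grid,
                                          surface_n=surface_n)
                except Exception as exc:   # per-row failure, never fatal
                    row = SweepRow(W_EE=float(W_EE), W_IE=float(W_IE),
                                   sigma_E=float(sE), sigma_I=float(sI),
                                   converged=False, error=str(exc))
                rows.append(row)
    return pd.DataFrame([r.__dict__ for r in rows])


SWEEP_PRESETS = ("excitation-grid", "representative-16", "noise-grid-mini")


def sweep_preset(name: str) -> SweepSpec:
    """Canonical survey grids over the recurrent-excitation plane.

    ``excitation-grid``: the dense 15x15 (W_EE, W_IE) grid from the
    asynchronous operating point up to 1.4x the strong-asynchronous
    strengths; ``representative-16``: sixteen representative members (4x4)
    per background-noise family; ``noise-grid-mini``: a 3x3 weight grid
    crossed with 12 (sigma_E, sigma_I) pairs spanning sigma_E in [1.5, 2.5]
    and sigma_I in [1.5, 3].
    """
    asyn = preset_config("asynchronous")
    strong = preset_config("strong_asynchronous")
    sig_asyn = (asyn["sigma_E"], asyn["sigma_I"])
    sig_strong = (strong["sigma_E"], strong["sigma_I"])
    if name == "excitation-grid":
        return SweepSpec(W_EE_values=list(np.linspace(0.5, 12.6, 15)),
                         W_IE_values=list(np.linspace(5.0, 11.2, 15)),
                         sigma_pairs=[sig_asyn], base_config=asyn)
    if name == "representative-16":
        return SweepSpec(W_EE_values=[0.5, 6.45, 9.0, 10.7],
                         W_IE_values=[5.0, 7.1, 8.0, 8.6],
                         sigma_pairs=[sig_asyn, sig_strong], base_config=asyn)
    if name == "noise-grid-mini":
        sig = [(a, b) for a in (1.5, 2.0, 2.5) for b in (1.5, 2.0, 2.5, 3.0)]
        return SweepSpec(W_EE_values=[0.5, 5.65, 10.8],
                         W_IE_values=[5.0, 7.3, 9.6],
                         sigma_pairs=sig, base_config=asyn)
    raise ValueError(f"unknown sweep preset {name!r}; available: "
                     f"{SWEEP_PRESETS}")
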