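"""Self-consistent firing rates of the recurrent network.

The network fixed point couples every cell's stationary rate to the rates of
its presynaptic partners: rates determine conductance moments (Poisson
shot-noise formulas), moments determine the effective single-cell diffusion,
and threshold integration of that diffusion returns new rates.  The damped
iteration

    nu <- (1 - gamma) nu + gamma Phi(nu)

starts from the uncoupled rates and stops when the fixed-point residual
max_i |Phi(nu)_i - nu_i| / max(nu_i, eps) drops below ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fokker_planck as fp
from .network_model import (Network, EffectiveCell, ConductanceMoments,
                            conductance_moments, effective_parameters)

__all__ = ["RateSolution", "PopulationSummary", "solve_network_rates",
           "population_summary"]


class RateInstabilityError(RuntimeError):
    """Raised when the iteration drives rates against the refractory bound."""


@dataclass
class RateSolution:
    """Converged (or flagged) network rate fixed point."""

    rates: np.ndarray              # spikes/ms, per cell
    cells: EffectiveCell           # effective parameters at the fixed point
    moments: ConductanceMoments
    iterations: int
    residual: float
    damping: float
    converged: bool

    @property
    def rates_hz(self) -> np.ndarray:
        return self.rates * 1e3


@dataclass
class PopulationSummary:
    """Population-averaged effective parameters (over E cells by default).

    ``sigma_gE``/``sigma_gI`` are averages of the per-cell conductance-noise
    *standard deviations*; ``sigma_sqrt_tau_m`` is the additive-noise
    amplitude sigma * sqrt(tau_m) as it enters the effective equation.
    """

    mean_gE: float
    mean_gI: float
    sigma_gE: float
    sigma_gI: float
    sigma_sqrt_tau_m: float
    E_rev: float
    rate: float                    # spikes/ms

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("mean_gE", "mean_gI", "sigma_gE", "sigma_gI",
                 "sigma_sqrt_tau_m", "E_rev", "rate")}


def _phi_map(network: Network, rates: np.ndarray,
             grid: fp.VoltageGrid | None):
    moments = conductance_moments(network, rates)
    cells = effective_parameters(network, moments)
    new_rates = fp.steady_rate(cells, grid)
    return new_rates, cells, moments


def solve_network_rates(network: Network, tol: float = 1e-6,
                        damping: float = 0.5, max_iter: int = 500,
                        grid: fp.VoltageGrid | None = None) -> RateSolution:
    """Damped fixed-point iteration for the network rates.

    Initializes at the uncoupled rates.  Returns ``converged=False`` (never
    silently) when ``max_iter`` is reached; raises ``RateInstabilityError``
    if any rate collides with the absolute refractory bound 1/tau_ref.
    """
    if not (0.0 < damping <= 1.0):
        raise ValueError("damping must lie in (0, 1]")
    # Freeze the voltage grid for the whole iteration: an adaptive lower
    # bound re-resolved per step perturbs the fixed-point map at the
    # discretization level and stalls convergence below ~1e-4.  The
    # uncoupled cells give a conservative (deep) bound because coupling
    # only increases g0, shrinking the stationary voltage spread.
    if grid is None or grid.v_min is None:
        base = grid or fp.VoltageGrid()
        cells0 = effective_parameters(
            network, conductance_moments(network, np.zeros(network.n_cells)))
        grid = fp.VoltageGrid(v_min=base.resolve_v_min(cells0),
                              n_points=base.n_points)
    rates = _phi_map(network, np.zeros(network.n_cells), grid)[0]
    residual = np.inf
    nu_max = 1.0 / network.intrinsic.tau_ref if network.intrinsic.tau_ref > 0 else np.inf
    for iteration in range(1, max_iter + 1):
        new_rates, cells, moments = _phi_map(network, rates, grid)
        # rates cannot exceed 1/tau_ref, but saturating against it means
        # the network has left any regime where the theory applies
        bad = new_rates >= 0.95 * nu_max
        if np.any(bad):
            raise RateInstabilityError(
                "rates approached the absolute refractory bound for cells "
                f"{np.flatnonzero(bad).tolist()}")
        scale = np.maximum(np.abs(rates), 1e-12)
        residual = float(np.max(np.abs(new_rates - rates) / scale))
        rates = (1.0 - damping) * rates + damping * new_rates
        if residual < tol:
            return RateSolution(rates=rates, cells=cells, moments=moments,
                                iterations=iteration, residual=residual,
                                damping=damping, converged=True)
    return RateSolution(rates=rates, cells=cells, moments=moments,
                        iterations=max_iter, residual=residual,
                        damping=damping, converged=False)


def population_summary(network: Network, solution: RateSolution,
                       over: str = "E_cells") -> PopulationSummary:
    """Arithmetic population means of the effective parameters.

    ``over`` selects E cells (default, matching the convention in which the
    printed additive-noise amplitude equals sigma_E sqrt(tau_m)) or all
    cells.
    """
    if over == "E_cells":
        mask = network.e_mask
        sigma = network.intrinsic.sigma_E
    elif over == "all_cells":
        mask = np.ones(network.n_cells, dtype=bool)
        sigma = float(np.mean(network.intrinsic.sigma_of(network.cell_type)))
    else:
        raise ValueError("over must be 'E_cells' or 'all_cells'")
    mom, cells = solution.moments, solution.cells
    from .network_model import E, I
    return PopulationSummary(
        mean_gE=float(np.mean(mom.mean_g[mask, E])),
        mean_gI=float(np.mean(mom.mean_g[mask, I])),
        sigma_gE=float(np.mean(np.sqrt(mom.var_g[mask, E]))),
        sigma_gI=float(np.mean(np.sqrt(mom.var_g[mask, I]))),
        sigma_sqrt_tau_m=float(sigma * np.sqrt(network.intrinsic.tau_m)),
        E_rev=float(np.mean(cells.E_rev[mask])),
        rate=float(np.mean(solution.rates[mask])))
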