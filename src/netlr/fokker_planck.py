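"""Threshold integration for the effective single-cell diffusion.

The reduced voltage equation of one cell is

    tau_m dv/dt = -g0 (v - E_rev) + sigma_gE xi_E (v - E_E)
                  + sigma_gI xi_I (v - E_I) + sigma sqrt(tau_m) xi,

with independent unit white noises, an absorbing threshold at theta,
re-injection at v_reset after a refractory delay tau_ref.  Interpreting the
multiplicative terms in the Ito sense, the Fokker-Planck flux is

    J(v) = mu(v) P - d/dv [D(v) P],
    mu(v) = -g0 (v - E_rev) / tau_m,
    D(v)  = [sigma^2 tau_m + sigma_gE^2 (v-E_E)^2 + sigma_gI^2 (v-E_I)^2]
            / (2 tau_m^2).

All quantities are obtained by integrating first-order ODEs in v backward
from threshold ("threshold integration"):

* stationary rate: the flux-normalized density p_hat solves
  d(D p_hat)/dv = mu p_hat - j with j = 1 between reset and threshold, and
  nu = 1 / (integral of p_hat + tau_ref);
* susceptibilities: the O(epsilon) response of the rate to a perturbation
  X -> X0 + X1 e^{i omega t} of one of the four channels (mean or variance
  of g_E or g_I) solves the same equations linearized around the stationary
  solution, with the modulated re-injection carrying a factor
  e^{-i omega tau_ref};
* the uncoupled power spectrum follows from the first-passage-time transform
  of the renewal threshold-reset process,
  C0(omega) = nu (1 - |F|^2) / |1 - F|^2 with F = e^{-i omega tau_ref} f_fp.

At omega = 0 the susceptibility is computed from stationary perturbation
theory (it equals d nu / dX exactly) and the spectrum from the first two
first-passage moments (C0(0) = nu CV^2), avoiding 0/0 limits.

Solvers are vectorized over batches of cells; the voltage recurrence uses
exact constant-coefficient exponential steps, which remain stable in the
small-noise (stiff) limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import EffectiveCell

__all__ = [
    "VoltageGrid",
    "default_frequency_grid",
    "CHANNELS",
    "steady_rate",
    "steady_state",
    "susceptibility",
    "susceptibility_zero",
    "power_spectrum_uncoupled",
    "isi_moments",
    "SusceptibilitySet",
    "compute_susceptibility_set",
]

CHANNELS = ("mean_gE", "mean_gI", "var_gE", "var_gI")


@dataclass(frozen=True)
class VoltageGrid:
    """Uniform voltage discretization from ``v_min`` up to each threshold.

    When ``v_min`` is None it adapts to the batch: five effective-voltage
    standard deviations below the lowest effective reversal potential (and
    never above E_I - 0.5).  At the background-noise magnitudes of interest
    the stationary density has a substantial Gaussian tail below the
    inhibitory reversal, so a fixed shallow bound would truncate mass and
    bias rates upward.
    """

    v_min: float | None = None
    n_points: int = 1024

    def __post_init__(self):
        if self.n_points < 256:
            raise ValueError("n_points must be at least 256")

    def resolve_v_min(self, cell: EffectiveCell) -> float:
        if self.v_min is not None:
            v_min = self.v_min
        else:
            # effective stationary voltage scale around E_rev
            var_v = (cell.sigma**2 * cell.tau_m
                     + cell.sigma_gE2 * (cell.E_rev - cell.E_E) ** 2
                     + cell.sigma_gI2 * (cell.E_rev - cell.E_I) ** 2
                     ) / (2.0 * cell.g0 * cell.tau_m)
            v_min = float(np.min(np.minimum(
                cell.E_rev - 5.0 * np.sqrt(var_v), cell.E_I - 0.5)))
        if v_min >= cell.v_reset:
            raise ValueError("v_min must lie below the reset voltage")
        return v_min


def default_frequency_grid() -> np.ndarray:
    """omega = 0 plus 64 log-spaced angular frequencies in [1e-3, 10] rad/ms."""
    return np.concatenate([[0.0], np.logspace(-3, 1, 64)])


class ThresholdIntegrationError(RuntimeError):
    """Raised when backward integration produces an invalid density/flux."""


def _drift_diffusion(cell: EffectiveCell, v: np.ndarray):
    """mu(v) and D(v) for a batch; ``v`` broadcasts against the batch axis."""
    mu = -cell.g0 * (v - cell.E_rev) / cell.tau_m
    D = (cell.sigma**2 * cell.tau_m
         + cell.sigma_gE2 * (v - cell.E_E) ** 2
         + cell.sigma_gI2 * (v - cell.E_I) ** 2) / (2.0 * cell.tau_m**2)
    return mu, D


def _grids(cell: EffectiveCell, grid: VoltageGrid):
    """Per-cell node positions (n, m), spacings (m,) and reset indices (m,)."""
    v_min = grid.resolve_v_min(cell)
    n = grid.n_points
    dv = (cell.theta - v_min) / (n - 1)
    k = np.arange(n)[:, None]
    v = v_min + k * dv[None, :]
    k_reset = np.rint((cell.v_reset - v_min) / dv).astype(int)
    k_reset = np.clip(k_reset, 1, n - 2)
    return v, dv, k_reset


_EXP_CLIP = 700.0


def _step_weights(a: np.ndarray, dv: np.ndarray):
    """Exact constant-coefficient step factors for q' = a q - j over -dv.

    Returns ``decay = e^{-a dv}`` and ``gain = (1 - e^{-a dv}) / a`` such
    that q_{k-1} = q_k * decay + j * gain.  Stable for |a dv| large (the
    exponent is clipped; the stiff limit gain -> 1/a is preserved).
    """
    x = a * dv
    with np.errstate(over="ignore"):
        decay = np.exp(-np.clip(x, -_EXP_CLIP, _EXP_CLIP))
    small = np.abs(x) < 1e-8
    safe_a = np.where(small, 1.0, a)
    with np.errstate(invalid="ignore"):
        gain = np.where(small, dv * (1.0 - 0.5 * x), (1.0 - decay) / safe_a)
    return decay, gain


def _backward_scalar(cell: EffectiveCell, grid: VoltageGrid,
                     source_nodes: np.ndarray | None = None,
                     flux_between_reset_and_threshold: float = 1.0):
    """Integrate d(q)/dv = (mu/D) q - j + b downward from q(theta) = 0.

    ``j`` is ``flux_between_reset_and_threshold`` above the reset node and 0
    below; ``b`` (optional) is an inhomogeneity given on nodes, shape (n, m).
    Returns q on nodes (q = D * density).  Uses the exact exponential step
    for piecewise-constant coefficients, evaluated at segment midpoints.
    """
    v, dv, k_reset = _grids(cell, grid)
    n, m = v.shape
    vm = v[1:, :] - 0.5 * dv[None, :]                    # segment midpoints
    mu_m, D_m = _drift_diffusion(cell, vm)
    if np.any(D_m <= 0):
        raise ThresholdIntegrationError(
            "diffusion coefficient vanishes on the grid; need sigma > 0 or "
            "nonzero conductance variance")
    a = mu_m / D_m                                       # (n-1, m)
    decay, gain = _step_weights(a, dv[None, :])
    seg_flux = (np.arange(1, n)[:, None] > k_reset[None, :]).astype(float)
    seg_flux *= flux_between_reset_and_threshold
    q = np.zeros((n, m))
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n - 1, 0, -1):
            b_seg = 0.0
            if source_nodes is not None:
                b_seg = 0.5 * (source_nodes[k] + source_nodes[k - 1])
            rhs = seg_flux[k - 1] - b_seg                # q' = a q - rhs
            q[k - 1] = q[k] * decay[k - 1] + rhs * gain[k - 1]
    return q, v, dv, k_reset


def _trapz(y: np.ndarray, dv: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (y.sum(axis=0) - 0.5 * (y[0] + y[-1])) * dv


def steady_state(cell: EffectiveCell, grid: VoltageGrid | None = None):
    """Stationary rate plus the flux-normalized density.

    Returns ``(nu, p_hat, v, dv, k_reset)`` where ``p_hat`` is the stationary
    density divided by the firing rate (P0 = nu * p_hat) and integrates to
    the mean first-passage time from reset to threshold.
    """
    grid = grid or VoltageGrid()
    q, v, dv, k_reset = _backward_scalar(cell, grid)
    if np.any(~np.isfinite(q)):
        # Density overflow: deterministic subthreshold cell, rate -> 0.
        q = np.where(np.isfinite(q), q, np.inf)
    if np.any(q < -1e-12 * np.nanmax(np.abs(q))):
        raise ThresholdIntegrationError(
            "negative probability flux encountered during threshold "
            f"integration (grid n={grid.n_points}, v_min={v[0, 0]:.3f})")
    _, D = _drift_diffusion(cell, v)
    p_hat = q / D
    m1 = _trapz(p_hat, dv)
    with np.errstate(divide="ignore"):
        nu = 1.0 / (m1 + cell.tau_ref)
    nu = np.where(np.isfinite(m1), nu, 0.0)
    return nu, p_hat, v, dv, k_reset


def steady_rate(cell: EffectiveCell, grid: VoltageGrid | None = None) -> np.ndarray:
    """Stationary firing rate (spikes/ms) of the threshold-reset process."""
    return steady_state(cell, grid)[0]


# --------------------------------------------------------------------------
# Channel perturbations
# --------------------------------------------------------------------------

def _channel_perturbation(cell: EffectiveCell, channel: str, v: np.ndarray):
    """First-order drift and diffusion perturbations (mu1, D1) for a unit
    modulation of the given channel."""
    if channel == "mean_gE":
        return -(v - cell.E_E) / cell.tau_m, None
    if channel == "mean_gI":
        return -(v - cell.E_I) / cell.tau_m, None
    if channel == "var_gE":
        return None, (v - cell.E_E) ** 2 / (2.0 * cell.tau_m**2)
    if channel == "var_gI":
        return None, (v - cell.E_I) ** 2 / (2.0 * cell.tau_m**2)
    raise ValueError(f"unknown perturbation channel {channel!r}; "
                     f"expected one of {CHANNELS}")


def susceptibility_zero(cell: EffectiveCell, channel: str,
                        grid: VoltageGrid | None = None) -> np.ndarray:
    """Zero-frequency susceptibility d nu / dX from stationary perturbation.

    Differentiates nu = 1/(m1 + tau_ref) through the stationary threshold
    integration: the perturbed q satisfies q1' = a q1 + a1 q with
    a1 = d(mu/D)/dX, and the density picks up an extra -q D1 / D^2 term.
    """
    grid = grid or VoltageGrid()
    nu, p_hat, v, dv, k_reset = steady_state(cell, grid)
    q = p_hat * _drift_diffusion(cell, v)[1]
    mu, D = _drift_diffusion(cell, v)
    mu1, D1 = _channel_perturbation(cell, channel, v)
    # a1 on nodes: d(mu/D)/dX = mu1/D - mu D1 / D^2
    a1 = np.zeros_like(v)
    if mu1 is not None:
        a1 += mu1 / D
    if D1 is not None:
        a1 -= mu * D1 / D**2
    source = a1 * q                                      # q1' = a q1 + (a1 q)
    q1, *_ = _backward_scalar(cell, grid, source_nodes=source,
                              flux_between_reset_and_threshold=0.0)
    p1 = q1 / D
    if D1 is not None:
        p1 = p1 - q * D1 / D**2
    dm1 = _trapz(p1, dv)
    return -(nu**2) * dm1


def _backward_spectral(cell: EffectiveCell, grid: VoltageGrid, omega: float,
                       boundary_flux: complex, reset_jump: complex,
                       source_nodes: np.ndarray | None = None):
    """Integrate the linearized spectral system downward from threshold.

        dJ/dv = -i omega r / D,   dr/dv = (mu/D) r - J + s(v),

    with r = D * P, J(theta) = boundary_flux, r(theta) = 0, and a flux jump
    of ``-reset_jump`` when crossing the reset node.  Returns J(v_min).
    Fourth-order Runge-Kutta with analytic coefficients at substeps.
    """
    v, dv, k_reset = _grids(cell, grid)
    n, m = v.shape
    J = np.full(m, boundary_flux, dtype=complex)
    r = np.zeros(m, dtype=complex)

    def coeff(vq):
        mu, D = _drift_diffusion(cell, vq)
        return mu / D, -1j * omega / D

    if source_nodes is None:
        src = None
    else:
        src = source_nodes

    for k in range(n - 1, 0, -1):
        h = -dv                                          # stepping downward
        v0 = v[k]
        s0 = src[k] if src is not None else 0.0
        s1 = 0.5 * (src[k] + src[k - 1]) if src is not None else 0.0
        s2 = src[k - 1] if src is not None else 0.0
        a0, c0 = coeff(v0)
        am, cm = coeff(v0 + 0.5 * h)
        a1, c1 = coeff(v0 + h)
        # RK4 for y' = f(v, y), y = (J, r)
        kJ1 = c0 * r
        kr1 = a0 * r - J + s0
        kJ2 = cm * (r + 0.5 * h * kr1)
        kr2 = am * (r + 0.5 * h * kr1) - (J + 0.5 * h * kJ1) + s1
        kJ3 = cm * (r + 0.5 * h * kr2)
        kr3 = am * (r + 0.5 * h * kr2) - (J + 0.5 * h * kJ2) + s1
        kJ4 = c1 * (r + h * kr3)
        kr4 = a1 * (r + h * kr3) - (J + h * kJ3) + s2
        J = J + (h / 6.0) * (kJ1 + 2 * kJ2 + 2 * kJ3 + kJ4)
        r = r + (h / 6.0) * (kr1 + 2 * kr2 + 2 * kr3 + kr4)
        at_reset = (k - 1) == k_reset
        if np.any(at_reset):
            J = J - np.where(at_reset, reset_jump, 0.0)
    return J


def susceptibility(cell: EffectiveCell, channel: str,
                   omega_grid: np.ndarray,
                   grid: VoltageGrid | None = None) -> np.ndarray:
    """Complex rate-modulation gain A_X(omega) for one perturbation channel.

    Linear response of the firing rate to X -> X0 + X1 e^{i omega t}; the
    omega = 0 entry equals the rate derivative d nu / dX.  Returns an array
    of shape (n_cells, n_omega).
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown perturbation channel {channel!r}; "
                         f"expected one of {CHANNELS}")
    grid = grid or VoltageGrid()
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    nu, p_hat, v, dv, k_reset = steady_state(cell, grid)
    P0 = nu[None, :] * p_hat
    mu1, D1 = _channel_perturbation(cell, channel, v)
    if mu1 is not None:
        source = mu1 * P0
    else:
        W = D1 * P0
        source = np.gradient(W, axis=0) / dv[None, :]
        source = -source
    out = np.empty((cell.n, omega_grid.size), dtype=complex)
    for fi, w in enumerate(omega_grid):
        if w == 0.0:
            out[:, fi] = susceptibility_zero(cell, channel, grid)
            continue
        phase = np.exp(-1j * w * cell.tau_ref)
        JA = _backward_spectral(cell, grid, w, boundary_flux=1.0,
                                reset_jump=phase)
        JB = _backward_spectral(cell, grid, w, boundary_flux=0.0,
                                reset_jump=0.0, source_nodes=source)
        out[:, fi] = -JB / JA
    return out


def _fpt_transform(cell: EffectiveCell, grid: VoltageGrid,
                   omega: float) -> np.ndarray:
    """Fourier transform of the first-passage-time density from reset to
    threshold, f(omega) = E[e^{-i omega T}]."""
    JA = _backward_spectral(cell, grid, omega, boundary_flux=1.0, reset_jump=0.0)
    JB = _backward_spectral(cell, grid, omega, boundary_flux=0.0, reset_jump=1.0)
    return -JB / JA


def isi_moments(cell: EffectiveCell, grid: VoltageGrid | None = None):
    """First two moments of the inter-spike interval (refractory included).

    Obtained from the small-omega expansion of the first-passage problem:
    two extra scalar backward passes give the mean and the second moment of
    the passage time; the refractory period shifts the mean only.
    """
    grid = grid or VoltageGrid()
    nu, p_hat, v, dv, k_reset = steady_state(cell, grid)
    m1 = _trapz(p_hat, dv)
    # J1(v) = -int_{v_min}^{v} p_hat: cumulative trapezoid up the grid
    mids = 0.5 * (p_hat[1:] + p_hat[:-1]) * dv[None, :]
    J1 = -np.concatenate([np.zeros((1, cell.n)), np.cumsum(mids, axis=0)])
    # second-order pass: r1' = a r1 - J1, i.e. inhomogeneity b = -J1
    q1, _, _, _ = _backward_scalar(cell, grid, source_nodes=-J1,
                                   flux_between_reset_and_threshold=0.0)
    _, D = _drift_diffusion(cell, v)
    P1 = q1 / D
    m2 = -2.0 * _trapz(P1, dv)
    mean_isi = cell.tau_ref + m1
    var_isi = m2 - m1**2
    return mean_isi, var_isi


def power_spectrum_uncoupled(cell: EffectiveCell, omega_grid: np.ndarray,
                             grid: VoltageGrid | None = None) -> np.ndarray:
    """Spike-train power spectral density of the uncoupled renewal process.

    C0(omega) = nu (1 - |F|^2) / |1 - F|^2 with F(omega) the Fourier
    transform of the full ISI density (refractory delay times the
    first-passage transform).  At omega = 0 this is nu CV^2; the spectrum
    approaches nu as omega -> infinity.
    """
    grid = grid or VoltageGrid()
    omega_grid = np.atleast_1d(np.asarray(omega_grid, dtype=float))
    nu, *_ = steady_state(cell, grid)
    out = np.empty((cell.n, omega_grid.size))
    # below ~1 spike per 10^15 ms the renewal normalization is pure noise
    zero_rate = nu <= 1e-15
    for fi, w in enumerate(omega_grid):
        if w == 0.0:
            mean_isi, var_isi = isi_moments(cell, grid)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv2 = var_isi / mean_isi**2
            out[:, fi] = np.where(zero_rate, 0.0, nu * cv2)
        else:
            F = np.exp(-1j * w * cell.tau_ref) * _fpt_transform(cell, grid, w)
            with np.errstate(divide="ignore", invalid="ignore"):
                s = nu * (1.0 - np.abs(F) ** 2) / np.abs(1.0 - F) ** 2
            out[:, fi] = np.where(zero_rate, 0.0, s)
    return out


# --------------------------------------------------------------------------
# Bundled per-network spectral quantities
# --------------------------------------------------------------------------

@dataclass
class SusceptibilitySet:
    """Frequency-resolved single-cell response functions for a batch.

    ``A[channel]`` has shape (n_cells, n_omega); ``C0`` is the uncoupled
    spike-train power spectrum on the same grid; ``nu`` the baseline rates.
    """

    omega: np.ndarray
    nu: np.ndarray
    A: dict
    C0: np.ndarray

    def at_zero(self, channel: str) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.omega)))
        return self.A[channel][:, idx].real

    @property
    def C0_zero(self) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.omega)))
        return self.C0[:, idx]


def compute_susceptibility_set(cell: EffectiveCell,
                               omega_grid: np.ndarray | None = None,
                               grid: VoltageGrid | None = None) -> SusceptibilitySet:
    """All four susceptibility channels plus the uncoupled power spectrum."""
    omega_grid = (default_frequency_grid() if omega_grid is None
                  else np.atleast_1d(np.asarray(omega_grid, dtype=float)))
    grid = grid or VoltageGrid()
    nu = steady_rate(cell, grid)
    A = {ch: susceptibility(cell, ch, omega_grid, grid) for ch in CHANNELS}
    C0 = power_spectrum_uncoupled(cell, omega_grid, grid)
    return SusceptibilitySet(omega=omega_grid, nu=nu, A=A, C0=C0)
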