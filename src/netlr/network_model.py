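"""Heterogeneous excitatory/inhibitory network model.

Each cell is a leaky integrate-and-fire neuron with dimensionless voltage,
driven by excitatory and inhibitory conductances with second-order
alpha-function kinetics and by additive Gaussian background noise:

    tau_m dv/dt = -v - g_E (v - E_E) - g_I (v - E_I) + sigma sqrt(tau_m) xi(t).

Heterogeneity enters through per-cell spike thresholds drawn as deterministic
quantiles of a log-normal distribution (mean 1, variance e^{cv^2} - 1).
Connectivity is Erdos-Renyi at type-dependent probabilities; the raw synaptic
weight W_YX is shared by all X->Y connections and divided by the realized
per-cell in-degree N_YX, so the mean synaptic drive is insensitive to the
in-degree while its variance scales like 1/N_YX.

Given per-cell firing rates, the module maps the network onto independent
"effective" single-cell diffusion processes: assuming presynaptic trains are
Poisson at the self-consistent rates, the stationary mean and variance of
each conductance are

    <g_X> = alpha_hat_X nu_X tau_rX,
    Var[g_X] = (alpha_hat_X^2 nu_X tau_rX / 2) * tau_rX / (tau_rX + tau_dX),

with nu_X the summed incoming rate of type-X spikes and alpha_hat_X the
per-synapse pulse amplitude alpha_X W_YX / N_YX.  The effective cell has leak
g0 = 1 + <g_E> + <g_I>, reversal E_rev = (<g_E> E_E + <g_I> E_I)/g0, and
multiplicative conductance noise with variances Var[g_E], Var[g_I].
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.special import ndtri

__all__ = [
    "IntrinsicParams",
    "SynapseKinetics",
    "CouplingSpec",
    "Network",
    "ConductanceMoments",
    "EffectiveCell",
    "sample_thresholds",
    "build_network",
    "conductance_moments",
    "effective_parameters",
    "load_config",
    "preset_config",
    "network_from_config",
    "PRESETS",
]

E, I = 0, 1  # channel / cell-type indices used throughout the package


@dataclass(frozen=True)
class IntrinsicParams:
    """Cell-intrinsic constants shared across the population.

    Times are in ms; voltages and noise magnitudes are dimensionless
    (threshold order 1).  ``sigma_E``/``sigma_I`` are the background-noise
    magnitudes of E and I cells as they appear in the voltage equation
    (the term sigma sqrt(tau_m) xi(t)).
    """

    tau_m: float = 20.0
    E_E: float = 6.5
    E_I: float = -0.5
    tau_ref: float = 2.0
    v_reset: float = 0.0
    sigma_E: float = 2.0 / np.sqrt(2.0)
    sigma_I: float = 3.0 / np.sqrt(2.0)

    def __post_init__(self):
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be nonnegative")
        if not (self.E_I < self.v_reset < self.E_E):
            raise ValueError("need E_I < v_reset < E_E")
        if self.sigma_E < 0 or self.sigma_I < 0:
            raise ValueError("noise magnitudes must be nonnegative")

    def sigma_of(self, cell_type: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(cell_type) == E, self.sigma_E, self.sigma_I)


@dataclass(frozen=True)
class SynapseKinetics:
    """Second-order alpha-synapse parameters per source type (E, I)."""

    alpha_E: float = 1.0
    alpha_I: float = 2.0
    tau_r_E: float = 1.0
    tau_d_E: float = 5.0
    tau_r_I: float = 2.0
    tau_d_I: float = 10.0

    def __post_init__(self):
        for name in ("alpha_E", "alpha_I", "tau_r_E", "tau_d_E", "tau_r_I", "tau_d_I"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def alpha(self) -> np.ndarray:
        return np.array([self.alpha_E, self.alpha_I])

    @property
    def tau_r(self) -> np.ndarray:
        return np.array([self.tau_r_E, self.tau_r_I])

    @property
    def tau_d(self) -> np.ndarray:
        return np.array([self.tau_d_E, self.tau_d_I])


@dataclass(frozen=True)
class CouplingSpec:
    """Raw synaptic weights and connection probabilities.

    Both arrays are indexed ``[target_type, source_type]`` with 0 = E, 1 = I.
    Weights are nonnegative; the sign of a connection comes from the reversal
    potential of its channel, not from W.
    """

    W: np.ndarray
    p_conn: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        p = np.asarray(self.p_conn, dtype=float)
        if W.shape != (2, 2) or p.shape != (2, 2):
            raise ValueError("W and p_conn must be 2x2 (target type, source type)")
        if np.any(W < 0):
            raise ValueError("synaptic weights must be nonnegative")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "p_conn", p)

    @classmethod
    def from_named(cls, W_EE, W_EI, W_IE, W_II, p_EE, p_EI, p_IE, p_II):
        """Build from the W_YX naming convention (Y = target, X = source)."""
        W = np.array([[W_EE, W_EI], [W_IE, W_II]], dtype=float)
        p = np.array([[p_EE, p_EI], [p_IE, p_II]], dtype=float)
        return cls(W=W, p_conn=p)


@dataclass
class Network:
    """A realized network: thresholds, adjacency and all parameters.

    ``adjacency[i, j]`` is True when there is a synapse j -> i (rows index
    the postsynaptic cell).  ``in_degree[i, X]`` counts presynaptic cells of
    type X.  Cells 0..N_E-1 are excitatory, the rest inhibitory.
    """

    N_E: int
    N_I: int
    theta: np.ndarray
    cell_type: np.ndarray
    adjacency: np.ndarray
    in_degree: np.ndarray
    intrinsic: IntrinsicParams
    synapses: SynapseKinetics
    coupling: CouplingSpec
    seed: int

    @property
    def n_cells(self) -> int:
        return self.N_E + self.N_I

    @property
    def e_mask(self) -> np.ndarray:
        return self.cell_type == E

    @property
    def i_mask(self) -> np.ndarray:
        return self.cell_type == I

    def alpha_hat(self) -> np.ndarray:
        """Per-cell, per-channel synaptic pulse amplitude alpha_X W_YX / N_YX.

        Zero where the realized in-degree from that type is zero (such cells
        simply receive no input of that type).
        """
        kin = self.synapses
        W_rows = self.coupling.W[self.cell_type, :]          # (N, 2): W_{Y_i, X}
        with np.errstate(divide="ignore", invalid="ignore"):
            ah = kin.alpha[None, :] * W_rows / self.in_degree
        ah[self.in_degree == 0] = 0.0
        return ah

    def with_weights(self, **named) -> "Network":
        """Copy of the network with raw weights replaced (W_EE=..., etc.),
        keeping the same connectivity realization."""
        W = self.coupling.W.copy()
        key_to_idx = {"W_EE": (E, E), "W_EI": (E, I), "W_IE": (I, E), "W_II": (I, I)}
        for key, val in named.items():
            W[key_to_idx[key]] = val
        return replace(self, coupling=CouplingSpec(W=W, p_conn=self.coupling.p_conn))


@dataclass
class ConductanceMoments:
    """Stationary conductance statistics per cell and channel (columns E, I).

    ``nu_in`` is the summed presynaptic rate per channel (spikes/ms) and
    ``alpha_hat`` the per-synapse pulse amplitude; together they determine
    mean and variance through the Poisson shot-noise formulas.
    """

    mean_g: np.ndarray
    var_g: np.ndarray
    nu_in: np.ndarray
    alpha_hat: np.ndarray


@dataclass
class EffectiveCell:
    """Parameters of the reduced single-cell diffusion (possibly batched).

    All fields broadcast together; scalar fields describe constants shared by
    the batch.  ``sigma_gE2``/``sigma_gI2`` are conductance-noise *variances*;
    ``sigma`` is the additive background magnitude entering as sigma^2 tau_m.
    """

    g0: np.ndarray
    E_rev: np.ndarray
    sigma_gE2: np.ndarray
    sigma_gI2: np.ndarray
    sigma: np.ndarray
    theta: np.ndarray
    tau_m: float = 20.0
    tau_ref: float = 2.0
    v_reset: float = 0.0
    E_E: float = 6.5
    E_I: float = -0.5

    def __post_init__(self):
        (self.g0, self.E_rev, self.sigma_gE2, self.sigma_gI2,
         self.sigma, self.theta) = np.broadcast_arrays(
            *(np.atleast_1d(np.asarray(x, dtype=float)) for x in
              (self.g0, self.E_rev, self.sigma_gE2, self.sigma_gI2,
               self.sigma, self.theta)))
        if np.any(self.g0 < 1.0 - 1e-12):
            raise ValueError("g0 = 1 + <g_E> + <g_I> cannot be below 1")
        if np.any(self.theta <= self.v_reset):
            raise ValueError("threshold must exceed the reset voltage")

    @property
    def n(self) -> int:
        return self.g0.shape[0]

    def take(self, idx) -> "EffectiveCell":
        idx = np.atleast_1d(idx)
        return EffectiveCell(
            g0=self.g0[idx], E_rev=self.E_rev[idx],
            sigma_gE2=self.sigma_gE2[idx], sigma_gI2=self.sigma_gI2[idx],
            sigma=self.sigma[idx], theta=self.theta[idx],
            tau_m=self.tau_m, tau_ref=self.tau_ref, v_reset=self.v_reset,
            E_E=self.E_E, E_I=self.E_I)


def sample_thresholds(n: int, cv_param: float, cdf_lo: float = 0.05,
                      cdf_hi: float = 0.95) -> np.ndarray:
    """Deterministic log-normal threshold quantiles.

    The distribution has mean 1 and variance ``e^{cv_param^2} - 1``, which
    pins the underlying normal to location ``-cv_param^2/2`` and scale
    ``cv_param``.  Quantiles are taken at ``n`` equally spaced CDF values in
    ``[cdf_lo, cdf_hi]`` (the midpoint 0.5 for ``n == 1``), so the same call
    always returns the same, monotonically increasing vector.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not (0.0 < cdf_lo <= cdf_hi < 1.0):
        raise ValueError("need 0 < cdf_lo <= cdf_hi < 1")
    if cv_param < 0:
        raise ValueError("cv_param must be nonnegative")
    if n == 1:
        p = np.array([0.5])
    else:
        p = cdf_lo + (cdf_hi - cdf_lo) * np.arange(n) / (n - 1)
    if cv_param == 0.0:
        return np.ones(n)
    s = cv_param
    mu = -0.5 * s * s
    return np.exp(mu + s * ndtri(p))


def build_network(N_E: int, N_I: int,
                  intrinsic: IntrinsicParams | None = None,
                  synapses: SynapseKinetics | None = None,
                  coupling: CouplingSpec | None = None,
                  seed: int = 0,
                  theta_cv: float = 0.2,
                  theta_cdf: tuple[float, float] = (0.05, 0.95),
                  degree_model: str = "fixed_in") -> Network:
    """Sample a network realization.

    With ``degree_model="fixed_in"`` (default) every cell receives exactly
    ``round(p_conn * N_X)`` connections from each source type, drawn without
    replacement; this keeps the per-synapse amplitude W_YX / N_YX uniform
    across the population, which is the regime in which population-averaged
    conductance statistics obey the homogeneous shot-noise relations.
    ``degree_model="bernoulli"`` instead draws each ordered pair independently
    at the type-pair probability (Erdos-Renyi).  No self-connections either
    way; thresholds are assigned from the deterministic log-normal quantiles
    separately for the E and I populations.  Reproducible for a fixed
    ``seed``.
    """
    if N_E < 1 or N_I < 1:
        raise ValueError("population sizes must be at least 1")
    intrinsic = intrinsic or IntrinsicParams()
    synapses = synapses or SynapseKinetics()
    if coupling is None:
        coupling = CouplingSpec.from_named(W_EE=0.5, W_EI=10.0, W_IE=5.0, W_II=5.0,
                                           p_EE=0.40, p_EI=0.35, p_IE=0.20, p_II=0.40)
    n = N_E + N_I
    cell_type = np.concatenate([np.zeros(N_E, dtype=int), np.ones(N_I, dtype=int)])
    rng = np.random.default_rng(seed)
    if degree_model == "bernoulli":
        P = coupling.p_conn[cell_type[:, None], cell_type[None, :]]
        adjacency = rng.random((n, n)) < P
        np.fill_diagonal(adjacency, False)
    elif degree_model == "fixed_in":
        adjacency = np.zeros((n, n), dtype=bool)
        pools = {E: np.flatnonzero(cell_type == E), I: np.flatnonzero(cell_type == I)}
        for i in range(n):
            for X in (E, I):
                pool = pools[X][pools[X] != i]
                k = int(round(coupling.p_conn[cell_type[i], X] * pools[X].size))
                k = min(k, pool.size)
                if k > 0:
                    adjacency[i, rng.choice(pool, size=k, replace=False)] = True
    else:
        raise ValueError("degree_model must be 'fixed_in' or 'bernoulli'")
    in_degree = np.stack([
        adjacency[:, cell_type == E].sum(axis=1),
        adjacency[:, cell_type == I].sum(axis=1)], axis=1)
    theta = np.concatenate([
        sample_thresholds(N_E, theta_cv, *theta_cdf),
        sample_thresholds(N_I, theta_cv, *theta_cdf)])
    for X, name in ((E, "E"), (I, "I")):
        missing = (in_degree[:, X] == 0) & (coupling.W[cell_type, X] > 0)
        if np.any(missing):
            warnings.warn(
                f"{int(missing.sum())} cell(s) have zero in-degree from type "
                f"{name} despite a nonzero weight; they receive no {name} input",
                stacklevel=2)
    return Network(N_E=N_E, N_I=N_I, theta=theta, cell_type=cell_type,
                   adjacency=adjacency, in_degree=in_degree,
                   intrinsic=intrinsic, synapses=synapses, coupling=coupling,
                   seed=seed)


def conductance_moments(network: Network, rates: np.ndarray) -> ConductanceMoments:
    """Poisson shot-noise moments of the synaptic conductances.

    All type-X presynaptic spikes onto a cell are pooled into one Poisson
    stream at the summed rate nu_X (spikes/ms); the second-order alpha
    filter then gives mean alpha_hat nu tau_r and variance
    (alpha_hat^2 nu tau_r / 2) tau_r / (tau_r + tau_d).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (network.n_cells,):
        raise ValueError("rates must have one entry per cell")
    if np.any(rates < 0):
        raise ValueError("firing rates must be nonnegative")
    kin = network.synapses
    A = network.adjacency
    nu_in = np.stack([
        A[:, network.e_mask] @ rates[network.e_mask],
        A[:, network.i_mask] @ rates[network.i_mask]], axis=1)
    ah = network.alpha_hat()
    tau_r, tau_d = kin.tau_r[None, :], kin.tau_d[None, :]
    mean_g = ah * nu_in * tau_r
    var_g = 0.5 * ah**2 * nu_in * tau_r * (tau_r / (tau_r + tau_d))
    return ConductanceMoments(mean_g=mean_g, var_g=var_g, nu_in=nu_in, alpha_hat=ah)


def effective_parameters(network: Network, moments: ConductanceMoments) -> EffectiveCell:
    """Reduce every cell to its effective diffusion parameters.

    g0 = 1 + <g_E> + <g_I>, E_rev = (<g_E> E_E + <g_I> E_I) / g0; the
    conductance variances pass through as multiplicative-noise magnitudes.
    """
    p = network.intrinsic
    mE, mI = moments.mean_g[:, E], moments.mean_g[:, I]
    g0 = 1.0 + mE + mI
    E_rev = (mE * p.E_E + mI * p.E_I) / g0
    return EffectiveCell(
        g0=g0, E_rev=E_rev,
        sigma_gE2=moments.var_g[:, E], sigma_gI2=moments.var_g[:, I],
        sigma=p.sigma_of(network.cell_type), theta=network.theta,
        tau_m=p.tau_m, tau_ref=p.tau_ref, v_reset=p.v_reset,
        E_E=p.E_E, E_I=p.E_I)


# --------------------------------------------------------------------------
# Configuration files and packaged presets
# --------------------------------------------------------------------------

PRESETS = ("asynchronous", "strong_asynchronous")


def load_config(path) -> dict:
    """Read a YAML/JSON network configuration into a flat dict."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def preset_config(name: str) -> dict:
    """Load one of the packaged preset configurations."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = importlib.resources.files("netlr") / "presets" / f"{name}.yaml"
    return yaml.safe_load(ref.read_text())


def network_from_config(cfg: dict, seed: int | None = None) -> Network:
    """Build a network from a configuration dict (see packaged presets)."""
    intrinsic = IntrinsicParams(
        tau_m=cfg.get("tau_m", 20.0), E_E=cfg.get("E_E", 6.5),
        E_I=cfg.get("E_I", -0.5), tau_ref=cfg.get("tau_ref", 2.0),
        v_reset=cfg.get("v_reset", 0.0),
        sigma_E=cfg["sigma_E"], sigma_I=cfg["sigma_I"])
    synapses = SynapseKinetics(
        alpha_E=cfg.get("alpha_E", 1.0), alpha_I=cfg.get("alpha_I", 2.0),
        tau_r_E=cfg.get("tau_r_E", 1.0), tau_d_E=cfg.get("tau_d_E", 5.0),
        tau_r_I=cfg.get("tau_r_I", 2.0), tau_d_I=cfg.get("tau_d_I", 10.0))
    pc = cfg["p_conn"]
    coupling = CouplingSpec.from_named(
        W_EE=cfg["W_EE"], W_EI=cfg["W_EI"], W_IE=cfg["W_IE"], W_II=cfg["W_II"],
        p_EE=pc["EE"], p_EI=pc["EI"], p_IE=pc["IE"], p_II=pc["II"])
    return build_network(
        N_E=cfg.get("N_E", 80), N_I=cfg.get("N_I", 20),
        intrinsic=intrinsic, synapses=synapses, coupling=coupling,
        seed=cfg.get("seed", 0) if seed is None else seed,
        theta_cv=cfg.get("theta_cv", 0.2),
        theta_cdf=(cfg.get("theta_cdf_lo", 0.05), cfg.get("theta_cdf_hi", 0.95)),
        degree_model=cfg.get("degree_model", "fixed_in"))
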