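"""Network cross-spectrum, long-time correlations and the motif expansion.

Each directed synapse j -> i contributes an entry of the interaction matrix

    K_ij(omega) = A_<gX>,i(omega) J_ij(omega) + A_var_gX,i(omega) L_ij(omega),

where X is the type of the source cell j, J is the synaptic filter of the
second-order alpha conductance,

    J(omega) = alpha_hat tau_r / [(1 + i omega tau_r)(1 + i omega tau_d)],

and L = J * (alpha_hat / 2) * tau_r / (tau_r + tau_d) is the corresponding
filter for the conductance *variance*.  The pairwise cross-spectrum of the
mean-shifted spike trains is

    C(omega) = (I - K)^{-1} C0(omega) (I - K)^{-H},

with C0 the diagonal matrix of uncoupled power spectra.  Expanding the
inverses in powers of K decomposes C into contributions from directed-path
motifs: order-k terms sum K^l C0 (K^H)^{k-l} over l = 0..k (chains and
common inputs of total length k).  The long-time Pearson spike-count
correlation is the omega = 0 cross-spectrum normalized by its diagonal.

The Fourier convention is f(omega) = int f(t) e^{-i omega t} dt with omega
in rad/ms; the headline statistics are all evaluated at omega = 0 and are
convention independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fokker_planck as fp
from .network_model import E, I, Network
from .self_consistency import RateSolution

__all__ = [
    "synaptic_filter", "variance_filter", "interaction_matrix",
    "cross_spectrum", "long_time_correlation", "motif_term",
    "second_order_split", "network_correlations", "InteractionMatrix",
    "CorrelationResult",
]


def synaptic_filter(omega, tau_r: float, tau_d: float, weight_hat: float):
    """Fourier transform of the conductance response to one presynaptic
    spike: a double low-pass with DC gain alpha_hat * tau_r."""
    omega = np.asarray(omega, dtype=float)
    return weight_hat * tau_r / ((1 + 1j * omega * tau_r) * (1 + 1j * omega * tau_d))


def variance_filter(omega, tau_r: float, tau_d: float, weight_hat: float):
    """Filter from presynaptic rate to conductance variance: the synaptic
    filter scaled by (alpha_hat/2) tau_r/(tau_r + tau_d), frequency
    independent relative to J."""
    return (synaptic_filter(omega, tau_r, tau_d, weight_hat)
            * 0.5 * weight_hat * tau_r / (tau_r + tau_d))


@dataclass
class InteractionMatrix:
    """K at a single frequency, with its building blocks for inspection."""

    omega: float
    K: np.ndarray                  # (N, N) complex; K_ij for synapse j -> i
    spectral_radius: float

    @classmethod
    def build(cls, network: Network, A_mean: dict, A_var: dict,
              omega: float) -> "InteractionMatrix":
        kin = network.synapses
        ah = network.alpha_hat()                       # (N, 2)
        adj = network.adjacency
        n = network.n_cells
        K = np.zeros((n, n), dtype=complex)
        for X, mean_ch, var_ch in ((E, "mean_gE", "var_gE"),
                                   (I, "mean_gI", "var_gI")):
            cols = network.cell_type == X
            tau_r, tau_d = kin.tau_r[X], kin.tau_d[X]
            J_row = synaptic_filter(omega, tau_r, tau_d, ah[:, X])
            L_row = variance_filter(omega, tau_r, tau_d, ah[:, X])
            gain = A_mean[mean_ch] * J_row + A_var[var_ch] * L_row   # (N,)
            K[:, cols] += np.where(adj[:, cols], gain[:, None], 0.0)
        rho = float(np.max(np.abs(np.linalg.eigvals(K)))) if n else 0.0
        return cls(omega=omega, K=K, spectral_radius=rho)


def interaction_matrix(network: Network, susc: fp.SusceptibilitySet,
                       omega: float = 0.0) -> InteractionMatrix:
    """Assemble K(omega) from a computed susceptibility set.

    ``omega`` must be on the set's frequency grid.  Entries vanish wherever
    the adjacency does; inhibitory columns carry negative omega = 0 entries
    for cells whose rate decreases with inhibition.
    """
    idx = np.flatnonzero(np.isclose(susc.omega, omega))
    if idx.size == 0:
        raise ValueError(f"omega={omega} is not on the susceptibility grid")
    fi = int(idx[0])
    A_mean = {ch: susc.A[ch][:, fi] for ch in ("mean_gE", "mean_gI")}
    A_var = {ch: susc.A[ch][:, fi] for ch in ("var_gE", "var_gI")}
    return InteractionMatrix.build(network, A_mean, A_var, susc.omega[fi])


class SpectralRadiusError(RuntimeError):
    """Raised when I - K is singular (linear response breaks down)."""


def cross_spectrum(C0_diag: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Full cross-spectral matrix (I-K)^{-1} diag(C0) (I-K)^{-H} at one
    frequency."""
    n = K.shape[0]
    ImK = np.eye(n) - K
    cond = np.linalg.cond(ImK)
    if not np.isfinite(cond) or cond > 1e12:
        rho = float(np.max(np.abs(np.linalg.eigvals(K))))
        raise SpectralRadiusError(
            f"I - K is numerically singular (spectral radius {rho:.4f})")
    Ainv = np.linalg.inv(ImK)
    C = Ainv @ np.diag(np.asarray(C0_diag, dtype=complex)) @ Ainv.conj().T
    return C


def long_time_correlation(C_zero: np.ndarray) -> np.ndarray:
    """Pearson matrix of long-window spike counts from the omega = 0
    cross-spectrum: rho_ij = C_ij / sqrt(C_ii C_jj)."""
    d = np.real(np.diag(C_zero)).copy()
    if np.any(d <= 0):
        raise ValueError("zero spike-count variance: correlation undefined "
                         f"for cells {np.flatnonzero(d <= 0).tolist()}")
    s = 1.0 / np.sqrt(d)
    rho = np.real(C_zero) * s[:, None] * s[None, :]
    np.fill_diagonal(rho, 1.0)
    return rho


def motif_term(C0_diag: np.ndarray, K: np.ndarray, k: int,
               norm: np.ndarray | None = None) -> np.ndarray:
    """Order-k contribution R^k = sum_l K^l C0 (K^H)^{k-l} / sqrt(C_ii C_jj).

    ``norm`` is the diagonal of the *total* cross-spectrum used for
    normalization; when omitted it is computed from the direct inverse.
    """
    if k < 0:
        raise ValueError("motif order k must be nonnegative")
    C0_diag = np.asarray(C0_diag, dtype=float)
    if norm is None:
        norm = np.real(np.diag(cross_spectrum(C0_diag, K)))
    C0m = np.diag(C0_diag.astype(complex))
    n = K.shape[0]
    term = np.zeros((n, n), dtype=complex)
    Kl = np.eye(n, dtype=complex)
    powers = [Kl]
    for _ in range(k):
        Kl = Kl @ K
        powers.append(Kl)
    KH = K.conj().T
    for l in range(k + 1):
        right = np.linalg.matrix_power(KH, k - l)
        term += powers[l] @ C0m @ right
    s = 1.0 / np.sqrt(norm)
    return np.real(term) * s[:, None] * s[None, :]


def second_order_split(C0_diag: np.ndarray, K: np.ndarray, network: Network,
                       norm: np.ndarray | None = None) -> dict:
    """Partition the order-2 motif term into its four mechanism classes.

    Common input K C0 K^H splits by the source-cell type (E_common,
    I_common).  The chain terms K^2 C0 + C0 (K^H)^2 split by the sign of
    each length-2 path's omega = 0 contribution: positive paths correlate
    the pair, negative paths decorrelate it.  The four matrices sum to the
    order-2 term exactly.
    """
    C0_diag = np.asarray(C0_diag, dtype=float)
    if norm is None:
        norm = np.real(np.diag(cross_spectrum(C0_diag, K)))
    s = 1.0 / np.sqrt(norm)
    Kr = np.real(K)
    common = {}
    for X, label in ((E, "E_common"), (I, "I_common")):
        cols = network.cell_type == X
        Ksub = Kr[:, cols]
        common[label] = (Ksub * C0_diag[cols][None, :]) @ Ksub.T
    # per-intermediate chain contributions: j -> l -> i and i -> l -> j
    chain_pos = np.zeros_like(Kr)
    chain_neg = np.zeros_like(Kr)
    for l in range(network.n_cells):
        # K^2 C0: paths source j -> l -> target i, weight K_il K_lj C0_jj
        p1 = np.outer(Kr[:, l], Kr[l, :]) * C0_diag[None, :]
        # C0 (K^H)^2: paths source i -> l -> target j, weight C0_ii K_jl K_li
        p2 = p1.T
        for p in (p1, p2):
            chain_pos += np.where(p > 0, p, 0.0)
            chain_neg += np.where(p < 0, p, 0.0)
    out = {label: M * s[:, None] * s[None, :] for label, M in
           (("E_common", common["E_common"]), ("I_common", common["I_common"]),
            ("chain_correlating", chain_pos), ("chain_decorrelating", chain_neg))}
    return out


@dataclass
class CorrelationResult:
    """Zero-frequency correlation structure of one network solution."""

    C0_diag: np.ndarray            # uncoupled power spectra at omega = 0
    K: np.ndarray                  # interaction matrix at omega = 0
    C: np.ndarray                  # full cross-spectrum at omega = 0
    rho: np.ndarray                # long-time Pearson matrix
    motif_terms: list              # R^0 .. R^k_max (normalized)
    split: dict                    # four-way order-2 mechanism split
    spectral_radius: float
    nu: np.ndarray                 # baseline rates (spikes/ms)

    @property
    def total_correlation(self) -> np.ndarray:
        """C_ij / sqrt(C_ii C_jj) including the diagonal."""
        return self.rho

    def pair_table(self, network: Network, pairs: str = "EE"):
        """Upper-triangle pair vectors for regression/plotting.

        Returns a dict of 1-D arrays (i, j, rho, R1..Rk, split terms)
        restricted to the requested pair class (EE, EI, II or all).
        """
        n = network.n_cells
        iu, ju = np.triu_indices(n, k=1)
        ti, tj = network.cell_type[iu], network.cell_type[ju]
        if pairs == "EE":
            keep = (ti == E) & (tj == E)
        elif pairs == "II":
            keep = (ti == I) & (tj == I)
        elif pairs == "EI":
            keep = ti != tj
        elif pairs == "all":
            keep = np.ones_like(iu, dtype=bool)
        else:
            raise ValueError("pairs must be EE, EI, II or all")
        iu, ju = iu[keep], ju[keep]
        out = {"i": iu, "j": ju, "rho": self.rho[iu, ju]}
        for k, Rk in enumerate(self.motif_terms):
            if k == 0:
                continue
            out[f"R{k}"] = Rk[iu, ju]
        for label, M in self.split.items():
            out[label] = M[iu, ju]
        return out


def network_correlations(network: Network, solution: RateSolution,
                         k_max: int = 4,
                         grid: fp.VoltageGrid | None = None) -> CorrelationResult:
    """Zero-frequency linear-response correlation analysis of a solved
    network: cross-spectrum, Pearson matrix, motif orders up to ``k_max``
    and the four-way second-order mechanism split."""
    cells = solution.cells
    omega0 = np.array([0.0])
    A_mean = {ch: fp.susceptibility_zero(cells, ch, grid)
              for ch in ("mean_gE", "mean_gI")}
    A_var = {ch: fp.susceptibility_zero(cells, ch, grid)
             for ch in ("var_gE", "var_gI")}
    Kmat = InteractionMatrix.build(network, A_mean, A_var, 0.0)
    C0_diag = fp.power_spectrum_uncoupled(cells, omega0, grid)[:, 0]
    C = cross_spectrum(C0_diag, Kmat.K)
    rho = long_time_correlation(C)
    norm = np.real(np.diag(C))
    motifs = [motif_term(C0_diag, Kmat.K, k, norm=norm) for k in range(k_max + 1)]
    split = second_order_split(C0_diag, Kmat.K, network, norm=norm)
    return CorrelationResult(C0_diag=C0_diag, K=np.real(Kmat.K), C=C, rho=rho,
                             motif_terms=motifs, split=split,
                             spectral_radius=Kmat.spectral_radius,
                             nu=solution.rates)
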