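"""Small deterministic networks for fast, analytic testing.

Every fixture uses the standard synapse kinetics so analytic constants
(such as the 1/12 variance-filter ratio for E synapses) remain valid; the
geometries isolate single mechanisms: an uncoupled pair (no correlation),
one inhibitory source shared by two targets (the common-input motif), a
feed-forward excitatory chain, a single directed edge (closed-form 2x2
cross-spectrum), and a miniature asynchronous-style recurrent network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_model import (CouplingSpec, IntrinsicParams, Network,
                            SynapseKinetics, build_network, sample_thresholds)

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("uncoupled_pair", "common_I_source", "ee_chain",
                 "two_by_two_analytic", "mini_asyn")


@dataclass
class Fixture:
    name: str
    network: Network
    seed: int
    notes: str = ""


def _manual_network(cell_type, adjacency, W, seed, theta=None,
                    sigma_E=None, sigma_I=None):
    cell_type = np.asarray(cell_type, dtype=int)
    adjacency = np.asarray(adjacency, dtype=bool)
    intr = IntrinsicParams()
    if sigma_E is not None or sigma_I is not None:
        intr = IntrinsicParams(sigma_E=sigma_E or intr.sigma_E,
                               sigma_I=sigma_I or intr.sigma_I)
    kin = SynapseKinetics()
    coupling = CouplingSpec(W=W, p_conn=np.zeros((2, 2)))
    n = cell_type.size
    if theta is None:
        theta = np.ones(n)
    in_degree = np.stack([adjacency[:, cell_type == 0].sum(1),
                          adjacency[:, cell_type == 1].sum(1)], axis=1)
    return Network(N_E=int(np.sum(cell_type == 0)),
                   N_I=int(np.sum(cell_type == 1)),
                   theta=np.asarray(theta, dtype=float),
                   cell_type=cell_type, adjacency=adjacency,
                   in_degree=in_degree, intrinsic=intr, synapses=kin,
                   coupling=coupling, seed=seed)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build one of the named fixtures (fully deterministic per name+seed)."""
    W_unit = np.ones((2, 2))
    if name == "uncoupled_pair":
        net = _manual_network([0, 0], np.zeros((2, 2)), np.zeros((2, 2)), seed)
        return Fixture(name, net, seed, "2 E cells, no edges: K = 0")
    if name == "common_I_source":
        # cell 2 (I) projects onto cells 0 and 1 (E)
        adj = np.zeros((3, 3))
        adj[0, 2] = adj[1, 2] = 1
        net = _manual_network([0, 0, 1], adj, W_unit, seed,
                              theta=[0.95, 1.05, 1.0])
        return Fixture(name, net, seed, "one I source shared by two E targets")
    if name == "ee_chain":
        # 0 -> 1 -> 2, all excitatory
        adj = np.zeros((3, 3))
        adj[1, 0] = adj[2, 1] = 1
        net = _manual_network([0, 0, 0], adj, W_unit, seed,
                              theta=[0.9, 1.0, 1.1])
        return Fixture(name, net, seed, "feed-forward E chain")
    if name == "two_by_two_analytic":
        adj = np.zeros((2, 2))
        adj[1, 0] = 1                      # single edge 0 -> 1
        net = _manual_network([0, 0], adj, W_unit, seed, theta=[0.95, 1.05])
        return Fixture(name, net, seed, "one directed E edge: closed-form "
                                        "2x2 cross-spectrum")
    if name == "mini_asyn":
        net = build_network(
            N_E=8, N_I=2, seed=seed,
            coupling=CouplingSpec.from_named(
                W_EE=0.5, W_EI=10.0, W_IE=5.0, W_II=5.0,
                p_EE=0.40, p_EI=1.0, p_IE=0.5, p_II=0.5))
        return Fixture(name, net, seed, "8E+2I scaled asynchronous-style "
                                        "network")
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
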