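"""Insulated heat diffusion on an interaction network.

Heat placed on a node spreads along edges by a random walk that retains a
fraction beta (the restart probability) at each step, giving the diffusion
operator F = beta * (I - (1-beta) W)^(-1) with W the column-normalized walk
matrix.  The exchanged-heat matrix E = F diag(h) records, in entry (i, j),
the heat node j passes to node i; its columns conserve the input heat h.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

from .io import InteractionNetwork

DEFAULT_BETA = 0.4
DEFAULT_HEAT_CAP = 1e-10


def heat_from_fdr(fdr, cap: float = DEFAULT_HEAT_CAP) -> np.ndarray:
    """Heat h = -log10(max(FDR, cap)); strong differential expression is hot.

    The cap keeps heat finite when a permutation FDR underflows.
    """
    fdr = np.asarray(fdr, dtype=float)
    if np.any((fdr <= 0) | (fdr > 1)):
        raise ValueError("FDR values must lie in (0, 1]")
    return -np.log10(np.maximum(fdr, cap))


@dataclass
class DiffusionOperator:
    """Dense insulated-diffusion matrix F over an ordered node list.

    Columns of F sum to 1 (heat conservation); all entries are
    non-negative.  Isolated nodes are removed before construction.
    """

    network: str
    nodes: list[str]
    beta: float
    F: np.ndarray

    def exchanged_heat(self, heat: np.ndarray) -> np.ndarray:
        """E = F diag(h): column j holds where node j's heat ends up."""
        heat = np.asarray(heat, dtype=float)
        if heat.shape != (len(self.nodes),):
            raise ValueError("heat vector does not match node list")
        if np.any(~np.isfinite(heat)) or np.any(heat < 0):
            raise ValueError("heat must be finite and non-negative")
        return self.F * heat[np.newaxis, :]


def build_diffusion(
    net: InteractionNetwork, beta: float = DEFAULT_BETA
) -> DiffusionOperator:
    """Construct F for a network by a dense linear solve.

    For beta in (0, 1) and column-stochastic W the system is strictly
    diagonally dominant, so the solve cannot be singular.
    """
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    nodes = sorted(n for n in net.graph.nodes if net.graph.degree(n) > 0)
    if not nodes:
        raise ValueError(f"network {net.name!r} has no connected nodes")
    n = len(nodes)
    adj = nx.to_numpy_array(net.graph, nodelist=nodes)
    W = adj / adj.sum(axis=0, keepdims=True)
    F = beta * scipy.linalg.solve(np.eye(n) - (1.0 - beta) * W, np.eye(n))
    return DiffusionOperator(network=net.name, nodes=nodes, beta=beta, F=F)
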