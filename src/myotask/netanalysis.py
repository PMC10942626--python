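"""Subnetwork analysis of extracted spatial muscle networks.

Node importance is measured with total communicability, the row sum of the
matrix exponential of the adjacency matrix,

    C(i) = sum_j [e^A]_ij,

which counts walks of every length with factorially decaying weight.  To
emphasise salient connectivity, edges whose communicability falls below
the average over existing edges are pruned (edge-level pruning keeps every
muscle on the body model; node-level pruning would disconnect muscles
outright, which is why it is not the default policy).  Submodules within a
spatial network come from monolayer modularity-based community detection.

Spatial factors live over muscle *pairs*, so a factor vector maps directly
onto the edges of a muscle network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from ._exceptions import ValidationError
from .modularity import ModularityParams, Partition, detect_communities

__all__ = [
    "CommunicabilityProfile",
    "communicability",
    "prune_below_average",
    "submodules",
    "factor_to_network",
]


@dataclass
class CommunicabilityProfile:
    node_total: np.ndarray   # C(i) per node, >= 1
    edge_matrix: np.ndarray  # e^A
    adj: np.ndarray          # the adjacency the profile was computed from


def communicability(adj) -> CommunicabilityProfile:
    """Total node communicability and the full e^A edge-communicability matrix."""
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    e = expm(a)
    return CommunicabilityProfile(e.sum(axis=1), e, a.copy())


def prune_below_average(adj, profile: CommunicabilityProfile) -> np.ndarray:
    """One-pass pruning of edges with below-average edge communicability.

    The average is taken over existing (nonzero-adjacency, off-diagonal)
    edges; an edge is retained iff its e^A entry is >= that mean.  Exactly
    one pass: re-application may prune further and is the caller's choice.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape != profile.adj.shape or not np.allclose(a, profile.adj):
        raise ValidationError("profile was not computed from this adjacency")
    mask_edges = (a > 0) & ~np.eye(a.shape[0], dtype=bool)
    if not mask_edges.any():
        warnings.warn("edgeless network: nothing to prune", stacklevel=2)
        return a.copy()
    mean_comm = profile.edge_matrix[mask_edges].mean()
    # ties at the mean are kept; tolerance absorbs expm round-off
    keep = profile.edge_matrix >= mean_comm * (1.0 - 1e-9)
    out = np.where(mask_edges & keep, a, 0.0)
    np.fill_diagonal(out, np.diag(a))
    return out


def submodules(adj, params: ModularityParams = ModularityParams(),
               n_repeats: int = 50, seed: int = 0) -> Partition:
    """Monolayer community detection on an extracted spatial network."""
    return detect_communities(np.asarray(adj, dtype=float), params=params,
                              n_repeats=n_repeats, seed=seed)


def factor_to_network(factor: np.ndarray, muscle_pairs, n_muscles: int,
                      support=None) -> np.ndarray:
    """Spatial factor vector (one weight per muscle pair) -> adjacency matrix.

    ``support`` (optional boolean per pair) restricts the network to the
    sparsified support.
    """
    factor = np.asarray(factor, dtype=float)
    if len(factor) != len(muscle_pairs):
        raise ValidationError("factor length must equal the number of muscle pairs")
    adj = np.zeros((n_muscles, n_muscles))
    for w, (i, j), s in zip(factor, muscle_pairs,
                            support if support is not None else np.ones(len(factor), bool)):
        if s:
            adj[i, j] = w
            adj[j, i] = w
    return adj
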