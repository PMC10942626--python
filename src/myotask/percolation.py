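"""Percolation-based sparsification of coupling networks.

Each network layer is pruned at its percolation threshold: edges are
removed in ascending weight order and the size of the giant connected
component is tracked against equivalently sized null networks (the same
layer with its weights shuffled over the same edges, so that removing the
k weakest null edges removes a uniformly random k-subset).  Removal stops
at the first step where the empirical giant-component fraction falls below
the chosen summary of the null fractions at the same density; the critical
threshold Pc is the weight of the last removed edge.

A layer only contributes significant couplings if its removal curve
separates from the null ensemble at all: strong couplings concentrated on
a subnetwork strand the remaining nodes once the weak scaffold is gone,
fragmenting the empirical giant component earlier than chance.  The mean
curve gap serves as a permutation statistic, corrected across a view's
layers by Benjamini-Hochberg; a layer indistinguishable from its nulls
carries no couplings above chance-level occurrence and empties.

Because couplings must be significant in both orientations, an entry of
the coupling tensor is retained only if its edge survives percolation in
its spatial layer AND in its temporal layer (a conservative conjunction).
Diagonal (t, t) entries of temporal layers are self-loops that cannot
affect connectivity; they are exempt from removal and survive the temporal
test whenever positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .coupling import CouplingTensor, NetworkLayerView, as_layers

__all__ = [
    "PercolationReport",
    "SparseCoupling",
    "giant_component_fraction",
    "percolation_threshold",
    "sparsify_layer",
    "sparsify_dual_domain",
    "sparsify_tensor",
]


@dataclass
class PercolationReport:
    """Outcome of percolation analysis on one layer.

    ``separation`` summarises how much earlier than chance the empirical
    giant component fragments under ascending-weight removal (mean gap to
    the null curve); ``p_value`` is its add-one permutation p-value over
    the null ensemble and ``significant`` marks p <= alpha — the
    signature of genuine weight-topology structure in the layer.
    """

    pc: float
    component_curve: np.ndarray  # giant fraction after 0..E removals
    null_curve: np.ndarray      # null summary at the same densities
    n_random: int
    removed_edges: list         # (i, j) in removal order
    seed: int
    statistic: str = "mean"
    separation: float = 0.0
    p_value: float = 1.0
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "pc": float(self.pc),
            "component_curve": [float(v) for v in self.component_curve],
            "null_curve": [float(v) for v in self.null_curve],
            "n_random": self.n_random,
            "removed_edges": [[int(i), int(j)] for i, j in self.removed_edges],
            "seed": int(self.seed),
            "statistic": self.statistic,
            "separation": float(self.separation),
            "p_value": float(self.p_value),
            "significant": bool(self.significant),
        }


@dataclass
class SparseCoupling:
    """Dual-domain sparsified coupling tensor."""

    mask: np.ndarray
    values: np.ndarray
    tensor: CouplingTensor = None
    reports: dict = field(default_factory=dict)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.max_size = 1 if n else 0

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.max_size = max(self.max_size, self.size[ra])


def giant_component_fraction(adj) -> float:
    """Largest connected component size over n, positive entries as edges."""
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    n = a.shape[0]
    uf = _UnionFind(n)
    ii, jj = np.nonzero(np.triu(a, 1) > 0)
    for i, j in zip(ii, jj):
        uf.union(int(i), int(j))
    return uf.max_size / n


def _edges_ascending(adj: np.ndarray):
    """Off-diagonal positive edges sorted by ascending weight (stable)."""
    iu, ju = np.triu_indices(adj.shape[0], 1)
    w = adj[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    return list(zip(iu[order], ju[order])), w[order]


def _removal_curve(n: int, edges, order: np.ndarray) -> np.ndarray:
    """Giant fraction after removing the first k edges of ``order``, k=0..E.

    Computed by adding edges in reverse with a union-find, so the whole
    curve costs O(E alpha(n)).
    """
    e = len(order)
    uf = _UnionFind(n)
    curve = np.empty(e + 1)
    curve[e] = uf.max_size / n
    for pos in range(e - 1, -1, -1):
        i, j = edges[order[pos]]
        uf.union(int(i), int(j))
        curve[pos] = uf.max_size / n
    return curve


def percolation_threshold(adj, n_random: int = 100, seed: int = 0,
                          statistic: str = "mean", percentile: float = 5.0,
                          alpha: float = 0.05) -> PercolationReport:
    """Percolation analysis of one symmetric nonnegative layer.

    statistic : "mean" compares the empirical giant fraction against the
        mean null fraction at the same density; "percentile" against the
        given lower percentile of the nulls.
    alpha : level of the layer-wise curve-separation test reported as
        ``significant`` (used by the dual-domain heuristic).
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    n = a.shape[0]
    edges, weights = _edges_ascending(a)
    e = len(edges)
    if e == 0:
        warnings.warn("empty layer: percolation skipped, Pc = 0", stacklevel=2)
        return PercolationReport(0.0, np.array([1.0 / max(n, 1)]), np.array([1.0 / max(n, 1)]),
                                 n_random, [], seed, statistic)
    if n_random < 20:
        raise ValidationError("need n_random >= 20 null networks")

    emp_curve = _removal_curve(n, edges, np.arange(e))

    rng = np.random.default_rng(seed)
    null = np.empty((n_random, e + 1))
    for r in range(n_random):
        null[r] = _removal_curve(n, edges, rng.permutation(e))
    if statistic == "mean":
        null_curve = null.mean(axis=0)
    elif statistic == "percentile":
        null_curve = np.percentile(null, percentile, axis=0)
    else:
        raise ValidationError(f"unknown null statistic {statistic!r}")

    n_removed = e
    for k in range(1, e + 1):
        if emp_curve[k] < null_curve[k]:
            n_removed = k - 1
            break

    # layer-wise structure test: does the empirical giant component
    # fragment earlier than the null ensemble's typical member?  (Strong
    # couplings concentrated on a subnetwork strand the remaining nodes
    # once the weak scaffold is removed, which weight-shuffled nulls
    # cannot reproduce.)  Add-one permutation p-value.
    null_mean = null.mean(axis=0)
    sep_emp = float((null_mean - emp_curve).mean())
    sep_null = (null_mean[None, :] - null).mean(axis=1)
    p_value = float((np.sum(sep_null >= sep_emp) + 1) / (n_random + 1))
    significant = p_value <= alpha

    pc = float(weights[n_removed - 1]) if n_removed > 0 else float(weights[0])
    removed = [tuple(map(int, edges[k])) for k in range(n_removed)]
    return PercolationReport(pc, emp_curve, null_curve, n_random, removed, seed,
                             statistic, sep_emp, p_value, significant)


def sparsify_layer(adj, report: PercolationReport) -> np.ndarray:
    """Zero out the removed edges; never increases any value."""
    out = np.asarray(adj, dtype=float).copy()
    for i, j in report.removed_edges:
        out[i, j] = 0.0
        out[j, i] = 0.0
    return out


def _benjamini_hochberg(p_values: np.ndarray, q: float) -> np.ndarray:
    """Boolean rejections controlling the false-discovery rate at q."""
    m = len(p_values)
    order = np.argsort(p_values)
    thresh = q * (np.arange(1, m + 1)) / m
    below = p_values[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        out[order[: k + 1]] = True
    return out


def _survival_masks(view: NetworkLayerView, n_random: int, seeds, statistic: str,
                    percentile: float, alpha: float):
    """Boolean survival matrix and report per layer matrix of a view.

    Layer-wise curve-separation p-values are corrected across the view's
    layers with Benjamini-Hochberg at rate ``alpha``; a layer whose
    removal curve never separates from its null ensemble carries no
    detectable weight-topology structure, so none of its edges count as
    significant.
    """
    masks = np.zeros_like(view.matrices, dtype=bool)
    reports = {}
    for idx, mat in enumerate(view.matrices):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = percolation_threshold(mat, n_random=n_random, seed=int(seeds[idx]),
                                        statistic=statistic, percentile=percentile,
                                        alpha=alpha)
        reports[view.keys[idx]] = rep
    keys = [view.keys[idx] for idx in range(len(view.matrices))]
    pvals = np.array([reports[k].p_value for k in keys])
    keep = _benjamini_hochberg(pvals, alpha)
    for idx, mat in enumerate(view.matrices):
        rep = reports[keys[idx]]
        rep.significant = bool(keep[idx])
        if rep.significant:
            surv = mat > 0
            for i, j in rep.removed_edges:
                surv[i, j] = False
                surv[j, i] = False
            masks[idx] = surv
    return masks, reports


def sparsify_dual_domain(spatial: NetworkLayerView, temporal: NetworkLayerView,
                         tensor: CouplingTensor, n_random: int = 100, seed: int = 0,
                         statistic: str = "mean", percentile: float = 5.0,
                         alpha: float = 0.05) -> SparseCoupling:
    """Retain entries surviving percolation in BOTH space and time.

    ``alpha`` is the Benjamini-Hochberg false-discovery rate applied to
    the layer-wise curve-separation p-values within each view.
    """
    if spatial.orientation != "spatial" or temporal.orientation != "temporal":
        raise ValidationError("views must be one spatial and one temporal")
    n_tp = len(tensor.time_pairs)
    n_mp = len(tensor.muscle_pairs)
    if len(spatial.matrices) != n_tp * tensor.n_layers or \
            len(temporal.matrices) != n_mp * tensor.n_layers:
        raise ValidationError("views do not derive from the given tensor")

    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(spatial.matrices) + len(temporal.matrices))
    s_masks, s_reports = _survival_masks(spatial, n_random, seeds[: len(spatial.matrices)],
                                         statistic, percentile, alpha)
    t_masks, t_reports = _survival_masks(temporal, n_random, seeds[len(spatial.matrices):],
                                         statistic, percentile, alpha)

    mask = np.zeros(tensor.values.shape, dtype=bool)
    for qi in range(n_tp):
        for li in range(tensor.n_layers):
            s_surv = s_masks[qi * tensor.n_layers + li]
            for pi, (i, j) in enumerate(tensor.muscle_pairs):
                t_surv = t_masks[pi * tensor.n_layers + li]
                t1, t2 = tensor.time_pairs[qi]
                ok_t = tensor.values[pi, qi, li] > 0 if t1 == t2 else t_surv[t1, t2]
                mask[pi, qi, li] = bool(s_surv[i, j]) and bool(ok_t)
    mask &= tensor.values > 0
    return SparseCoupling(mask, tensor.values * mask, tensor,
                          {"spatial": s_reports, "temporal": t_reports})


def sparsify_tensor(tensor: CouplingTensor, n_random: int = 100, seed: int = 0,
                    statistic: str = "mean", percentile: float = 5.0,
                    alpha: float = 0.05) -> SparseCoupling:
    """Convenience: build both views from the tensor and sparsify dually."""
    return sparsify_dual_domain(as_layers(tensor, "spatial"), as_layers(tensor, "temporal"),
                                tensor, n_random=n_random, seed=seed,
                                statistic=statistic, percentile=percentile, alpha=alpha)
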