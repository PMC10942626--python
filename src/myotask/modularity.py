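"""Model-rank selection by modularity-maximising community detection.

The number of spatial and temporal factors to extract is not a free
parameter: it is read off the modular structure of the sparsified coupling
networks.  Monolayer modularity is the Newman-Girvan Q-statistic

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(g_i, g_j),   m = 1/2 sum A

and its multilayer generalisation adds an inter-layer coupling term with
intra-/inter-layer resolution parameters gamma and omega (both 1 here,
i.e. classical modularity, no hyperparameter tuning).  Communities are
found with a seeded greedy local-moving optimiser (Louvain-style) with
restarts; per-participant/task partitions are then combined through a
consensus step — co-classification matrices are stacked into a new
multiplex network and detection is re-applied — whose community count is
the model rank.

Both the monolayer-per-layer and the joint multilayer routes are run; the
multilayer result is the default and any disagreement is recorded in the
rank's provenance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import MyotaskError, ValidationError

__all__ = [
    "Partition",
    "ModularityParams",
    "ModelRank",
    "modularity_mono",
    "modularity_multi",
    "detect_communities",
    "consensus_model_rank",
    "select_model_rank",
]


@dataclass(frozen=True)
class Partition:
    """Node -> community assignment with ids contiguous from 1."""

    assignment: tuple

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment))

    @staticmethod
    def from_labels(labels) -> "Partition":
        labels = list(labels)
        remap = {}
        out = []
        for lab in labels:
            if lab not in remap:
                remap[lab] = len(remap) + 1
            out.append(remap[lab])
        return Partition(tuple(out))


@dataclass(frozen=True)
class ModularityParams:
    gamma: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.omega < 0:
            raise ValidationError("require gamma > 0 and omega >= 0")


@dataclass
class ModelRank:
    spatial: int
    temporal: int
    provenance: dict = field(default_factory=dict)


def _check_adj(adj) -> np.ndarray:
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.allclose(a, a.T):
        raise ValidationError("adjacency must be symmetric")
    if (a < 0).any():
        raise ValidationError("adjacency must be nonnegative")
    return a


def modularity_mono(adj, partition: Partition, gamma: float = 1.0) -> float:
    """Newman-Girvan modularity of a partition on one layer."""
    a = _check_adj(adj)
    two_m = a.sum()
    if two_m == 0:
        raise MyotaskError("modularity undefined for an edgeless network")
    k = a.sum(axis=1)
    g = np.asarray(partition.assignment)
    same = g[:, None] == g[None, :]
    b = a - gamma * np.outer(k, k) / two_m
    return float((b * same).sum() / two_m)


def modularity_multi(layers, partitions, params: ModularityParams = ModularityParams()) -> float:
    """Multilayer modularity with categorical all-to-all inter-layer coupling.

    ``partitions`` is one :class:`Partition` per layer over a common node
    set.  Reduces exactly to :func:`modularity_mono` for a single layer
    with gamma = 1.
    """
    mats = [_check_adj(a) for a in layers]
    n = mats[0].shape[0]
    n_layers = len(mats)
    if any(m.shape[0] != n for m in mats):
        raise ValidationError("layers must share a node set")
    if len(partitions) != n_layers:
        raise ValidationError("need one partition per layer")
    g = np.asarray([p.assignment for p in partitions])  # (L, n)

    intra = 0.0
    total_weight = 0.0
    for li, a in enumerate(mats):
        two_m = a.sum()
        total_weight += two_m
        if two_m == 0:
            continue
        k = a.sum(axis=1)
        same = g[li][:, None] == g[li][None, :]
        intra += ((a - params.gamma * np.outer(k, k) / two_m) * same).sum()

    inter = 0.0
    coupling_weight = 0.0
    if n_layers > 1 and params.omega > 0:
        for li in range(n_layers):
            for lr in range(n_layers):
                if li == lr:
                    continue
                coupling_weight += params.omega * n
                inter += params.omega * np.sum(g[li] == g[lr])

    two_mu = total_weight + coupling_weight
    if two_mu == 0:
        raise MyotaskError("modularity undefined for an edgeless multiplex")
    return float((intra + inter) / two_mu)


def _supra_matrix(layers, params: ModularityParams):
    """Supra-modularity matrix B and normalisation 2*mu for greedy moves."""
    mats = [np.asarray(a, dtype=float) for a in layers]
    n = mats[0].shape[0]
    n_layers = len(mats)
    size = n * n_layers
    b = np.zeros((size, size))
    total_weight = 0.0
    for li, a in enumerate(mats):
        two_m = a.sum()
        total_weight += two_m
        sl = slice(li * n, (li + 1) * n)
        if two_m == 0:
            continue
        k = a.sum(axis=1)
        b[sl, sl] = a - params.gamma * np.outer(k, k) / two_m
    coupling_weight = 0.0
    if n_layers > 1 and params.omega > 0:
        for li in range(n_layers):
            for lr in range(n_layers):
                if li == lr:
                    continue
                idx = np.arange(n)
                b[li * n + idx, lr * n + idx] += params.omega
                coupling_weight += params.omega * n
    return b, total_weight + coupling_weight, n, n_layers


def _local_moves(b: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One round of greedy modularity local moving; returns True if changed.

    Ties between equally good target communities break toward the lowest
    community index for determinism under a fixed seed.
    """
    n = b.shape[0]
    changed = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            current = labels[i]
            strengths = {}
            for j in range(n):
                if j == i:
                    continue
                strengths[labels[j]] = strengths.get(labels[j], 0.0) + b[i, j]
            base = strengths.get(current, 0.0)
            best_gain, best_c = 0.0, current
            for c in sorted(strengths):
                if c == current:
                    continue
                gain = strengths[c] - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, c
            if best_c != current:
                labels[i] = best_c
                improved = True
                changed = True
    return changed


def _greedy_local_moves(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Louvain-style optimisation on a supra-modularity matrix.

    Alternates greedy local moving with community aggregation (communities
    condensed to super-nodes, the quality matrix summed accordingly) until
    neither phase improves the partition.
    """
    n = b.shape[0]
    labels = np.arange(n)
    while True:
        work = b.copy()
        np.fill_diagonal(work, 0.0)
        # map current communities to contiguous ids and condense
        uniq, comm = np.unique(labels, return_inverse=True)
        k = len(uniq)
        agg = np.zeros((k, k))
        for c in range(k):
            sel = comm == c
            agg[c] = work[sel].sum(axis=0) @ _indicator(comm, k)
        np.fill_diagonal(agg, 0.0)
        meta = np.arange(k)
        if not _local_moves(agg, meta, rng):
            break
        labels = meta[comm]
    return labels


def _indicator(comm: np.ndarray, k: int) -> np.ndarray:
    ind = np.zeros((len(comm), k))
    ind[np.arange(len(comm)), comm] = 1.0
    return ind


def detect_communities(network, params: ModularityParams = ModularityParams(),
                       n_repeats: int = 50, seed: int = 0) -> Partition:
    """Best-of-restarts greedy community detection.

    ``network`` is a single symmetric adjacency (monolayer) or a sequence
    of aligned layers (multiplex; categorical omega-coupling).  For a
    multiplex input the returned partition assigns each node its modal
    community across layers.  Never returns a partition with lower Q than
    the all-in-one partition.
    """
    if isinstance(network, np.ndarray):
        layers = [network] if network.ndim == 2 else list(network)
    else:
        network = list(network)
        layers = network if np.asarray(network[0]).ndim == 2 else [np.asarray(network)]
    layers = [_check_adj(a) for a in layers]
    if all(a.sum() == 0 for a in layers):
        raise ValidationError("cannot detect communities in an edgeless network")
    b, two_mu, n, n_layers = _supra_matrix(layers, params)

    rng = np.random.default_rng(seed)
    best_q, best_labels = -np.inf, None
    for _ in range(max(1, n_repeats)):
        labels = _greedy_local_moves(b, rng)
        same = labels[:, None] == labels[None, :]
        q = (b * same).sum() / two_mu
        if q > best_q:
            best_q, best_labels = q, labels

    # guard: the trivial all-in-one partition is always a candidate
    q_one = b.sum() / two_mu
    if q_one > best_q:
        best_labels = np.zeros(n * n_layers, dtype=int)

    per_layer = best_labels.reshape(n_layers, n)
    node_labels = [Counter(per_layer[:, i]).most_common(1)[0][0] for i in range(n)]
    return Partition.from_labels(node_labels)


def consensus_model_rank(partitions, seed: int = 0,
                         params: ModularityParams = ModularityParams(),
                         n_repeats: int = 50) -> tuple[int, dict]:
    """Consensus community count over a set of partitions.

    Each partition is turned into a binary co-classification matrix
    (1 iff two nodes share a community); the matrices are stacked as a
    multiplex network and community detection is re-applied.  The number
    of consensus communities is the model rank.  Idempotent: consensus of
    copies of one partition returns that partition's community count.
    """
    parts = list(partitions)
    if len(parts) < 2:
        raise ValidationError("need >= 2 partitions for consensus")
    n = len(parts[0].assignment)
    if any(len(p.assignment) != n for p in parts):
        raise ValidationError("partitions must cover a common node set")
    layers = []
    for p in parts:
        g = np.asarray(p.assignment)
        mat = (g[:, None] == g[None, :]).astype(float)
        np.fill_diagonal(mat, 0.0)
        layers.append(mat)
    consensus = detect_communities(layers, params=params, n_repeats=n_repeats, seed=seed)
    trace = {
        "n_input_partitions": len(parts),
        "input_ranks": [p.n_communities for p in parts],
        "consensus_assignment": list(consensus.assignment),
        "agreement": float(np.mean([p.assignment == consensus.assignment for p in parts])),
    }
    return consensus.n_communities, trace


def _nonempty(mats) -> list:
    return [m for m in mats if m.sum() > 0]


def _rank_for_orientation(view_matrices, keys, n_layers: int, params, n_repeats, rng_seeds):
    """Both-route rank selection for one orientation.

    view_matrices are grouped by tensor layer; the multilayer route runs
    multiplex detection per group, the monolayer route runs detection per
    matrix, and both feed the consensus step.
    """
    groups = {}
    for mat, (other_idx, li) in zip(view_matrices, keys):
        groups.setdefault(li, []).append(mat)

    multi_parts, mono_parts = [], []
    for gi, (li, mats) in enumerate(sorted(groups.items())):
        mats = _nonempty(mats)
        if not mats:
            continue
        multi_parts.append(detect_communities(mats, params=params, n_repeats=n_repeats,
                                              seed=int(rng_seeds[gi])))
        for mi, m in enumerate(mats):
            mono_parts.append(detect_communities(m, params=params, n_repeats=max(5, n_repeats // 5),
                                                 seed=int(rng_seeds[gi]) + mi + 1))
    if len(multi_parts) == 0:
        return 1, 1, {"note": "all layers empty; rank defaulted to 1"}
    if len(multi_parts) == 1:
        rank_multi, trace_multi = multi_parts[0].n_communities, {"single_group": True}
    else:
        rank_multi, trace_multi = consensus_model_rank(multi_parts, seed=int(rng_seeds[-1]),
                                                       params=params, n_repeats=n_repeats)
    if len(mono_parts) == 1:
        rank_mono, trace_mono = mono_parts[0].n_communities, {"single_group": True}
    else:
        rank_mono, trace_mono = consensus_model_rank(mono_parts, seed=int(rng_seeds[-2]),
                                                     params=params, n_repeats=n_repeats)
    trace = {"multilayer": {"rank": rank_multi, "trace": trace_multi},
             "monolayer": {"rank": rank_mono, "trace": trace_mono},
             "agree": rank_multi == rank_mono}
    return rank_multi, rank_mono, trace


def select_model_rank(sparse, params: ModularityParams = ModularityParams(),
                      n_repeats: int = 50, seed: int = 0) -> ModelRank:
    """Spatial and temporal model ranks from a sparsified coupling tensor.

    Runs the multilayer and monolayer detection routes in both
    orientations and takes the multilayer consensus as the rank,
    recording both in the provenance.
    """
    from .coupling import as_layers

    tensor = sparse.tensor.copy_with(sparse.values) if sparse.tensor is not None else None
    if tensor is None:
        raise ValidationError("sparse coupling lacks its parent tensor")
    sp = as_layers(tensor, "spatial")
    tp = as_layers(tensor, "temporal")
    ss = np.random.SeedSequence(seed)
    seeds_sp = ss.generate_state(len(sp.matrices) + 2)
    seeds_tp = ss.generate_state(len(tp.matrices) + 2)
    s_multi, s_mono, s_trace = _rank_for_orientation(sp.matrices, sp.keys, tensor.n_layers,
                                                     params, n_repeats, seeds_sp)
    t_multi, t_mono, t_trace = _rank_for_orientation(tp.matrices, tp.keys, tensor.n_layers,
                                                     params, n_repeats, seeds_tp)
    return ModelRank(spatial=s_multi, temporal=t_multi,
                     provenance={"spatial": s_trace, "temporal": t_trace})
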