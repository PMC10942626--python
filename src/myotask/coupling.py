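"""Assembly of the multiplex coupling tensor.

Every unique muscle-timepoint vector pair ``[mx(t1), my(t2)]`` is scored
against every task variable for every participant, producing a nonnegative
tensor of shape

    (muscle pairs) x (timepoint pairs) x (task variables x participants)

for each of the three interaction classes: ``irrelevant`` (conditional MI
given the task), ``redundant`` and ``synergistic`` (rectified negative and
positive halves of the signed co-information, produced in one pass).

Muscle pairs exclude self-pairs (self-MI is an entropy, not a coupling);
timepoint pairs include the diagonal (t, t), where temporally proximal
dependencies live.  For continuous task variables the marginal MIs use the
task sample at each member's own timepoint and the joint MI uses the
stacked pair of task samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._exceptions import ValidationError
from .information import TaskVariable, cmi, co_information
from .preprocessing import ProcessedEMG

__all__ = [
    "CouplingTensor",
    "NetworkLayerView",
    "enumerate_pairs",
    "build_tensor",
    "build_tensors",
    "as_layers",
    "tensor_from_layers",
]

INTERACTIONS = ("irrelevant", "redundant", "synergistic")


@dataclass
class CouplingTensor:
    """MI/co-I couplings over muscle pairs, timepoint pairs, and layers."""

    values: np.ndarray  # (n_muscle_pairs, n_time_pairs, n_layers), >= 0
    muscle_pairs: list
    time_pairs: list
    layer_labels: list  # (task name, participant index) per layer
    interaction: str
    n_muscles: int
    n_timepoints: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("coupling tensor must be 3-D")
        if (self.values < 0).any():
            raise ValidationError("coupling tensor must be nonnegative")
        if self.interaction not in INTERACTIONS:
            raise ValidationError(f"unknown interaction class {self.interaction!r}")

    @property
    def n_layers(self) -> int:
        return self.values.shape[2]

    def copy_with(self, values: np.ndarray) -> "CouplingTensor":
        return CouplingTensor(values, list(self.muscle_pairs), list(self.time_pairs),
                              list(self.layer_labels), self.interaction,
                              self.n_muscles, self.n_timepoints)


@dataclass
class NetworkLayerView:
    """Stack of symmetric adjacency matrices in one orientation.

    spatial : one (n_muscles x n_muscles) matrix per (time pair, layer).
    temporal : one (T x T) matrix per (muscle pair, layer), diagonal included.
    ``keys`` records (pair index in the other domain, layer index) per matrix.
    """

    orientation: str
    matrices: np.ndarray
    keys: list = field(default_factory=list)


def enumerate_pairs(n: int, include_diagonal: bool = False) -> list:
    """All unordered index pairs; (i, i) pairs only when requested."""
    if n < 2:
        raise ValidationError("need at least 2 items to enumerate pairs")
    pairs = list(combinations(range(n), 2))
    if include_diagonal:
        pairs = sorted(pairs + [(i, i) for i in range(n)])
    return pairs


def _tau_slices(tau: TaskVariable, t1: int, t2: int):
    """Task samples for a timepoint pair under the own-timepoint pairing policy.

    Returns (tau_x, tau_y, tau_joint): marginal samples at each member's own
    timepoint and the stacked joint sample (deduplicated when t1 == t2).
    """
    if tau.kind == "discrete":
        return tau, tau, tau
    z1 = tau.values[:, t1][:, None]
    z2 = tau.values[:, t2][:, None]
    zj = z1 if t1 == t2 else np.column_stack([z1, z2])
    return z1, z2, zj


def build_tensors(emg, tasks) -> dict:
    """Compute all three interaction-class tensors in one pass.

    Parameters
    ----------
    emg : ProcessedEMG or list of ProcessedEMG (one per participant).
    tasks : list of TaskVariable, each aligned with the trials of every
        participant's envelope.

    Returns a dict ``{"irrelevant": ..., "redundant": ..., "synergistic": ...}``
    of :class:`CouplingTensor`.
    """
    if isinstance(emg, ProcessedEMG):
        emg = [emg]
    if not emg or not tasks:
        raise ValidationError("need at least one participant and one task variable")
    n_muscles = emg[0].n_muscles
    n_time = emg[0].n_timepoints
    if n_muscles < 2 or n_time < 2:
        raise ValidationError("need >= 2 muscles and >= 2 timepoints")
    for e in emg:
        if e.n_muscles != n_muscles or e.n_timepoints != n_time:
            raise ValidationError("participants must share muscle and timepoint counts")

    mpairs = enumerate_pairs(n_muscles, include_diagonal=False)
    tpairs = enumerate_pairs(n_time, include_diagonal=True)
    layer_labels = [(tau.name, p) for tau in tasks for p in range(len(emg))]
    shape = (len(mpairs), len(tpairs), len(layer_labels))
    out = {cls: np.zeros(shape) for cls in INTERACTIONS}

    for li, (tau, p) in enumerate((tau, p) for tau in tasks for p in range(len(emg))):
        env = emg[p].envelope
        for qi, (t1, t2) in enumerate(tpairs):
            tau_x, tau_y, tau_j = _tau_slices(tau, t1, t2)
            for pi, (i, j) in enumerate(mpairs):
                mx = env[:, i, t1]
                my = env[:, j, t2]
                try:
                    cond = cmi(mx, my, tau_j if tau.kind == "continuous" else tau)
                    coi = _coi_pair(mx, my, tau, tau_x, tau_y, tau_j)
                except Exception as err:  # annotate estimator failures with context
                    raise ValidationError(
                        f"estimation failed for muscle pair {(i, j)}, timepoint pair "
                        f"{(t1, t2)}, layer {layer_labels[li]}: {err}"
                    ) from err
                out["irrelevant"][pi, qi, li] = cond.value
                out["redundant"][pi, qi, li] = max(0.0, -coi)
                out["synergistic"][pi, qi, li] = max(0.0, coi)

    return {
        cls: CouplingTensor(out[cls], mpairs, tpairs, layer_labels, cls, n_muscles, n_time)
        for cls in INTERACTIONS
    }


def _coi_pair(mx, my, tau: TaskVariable, tau_x, tau_y, tau_j) -> float:
    """Signed co-information for one muscle-timepoint pair."""
    if tau.kind == "discrete":
        return co_information(mx, my, tau).value
    # continuous: marginals at own timepoints, joint against the stacked pair
    from .information import _LN2, _mi_gc_nats, copula_normalize

    cx = copula_normalize(mx)[:, None]
    cy = copula_normalize(my)[:, None]
    czx = copula_normalize(tau_x)
    czy = copula_normalize(tau_y)
    czj = copula_normalize(tau_j)
    if czx.ndim == 1:
        czx = czx[:, None]
    if czy.ndim == 1:
        czy = czy[:, None]
    if czj.ndim == 1:
        czj = czj[:, None]
    mi_x = _mi_gc_nats(cx, czx) / _LN2
    mi_y = _mi_gc_nats(cy, czy) / _LN2
    mi_joint = _mi_gc_nats(np.column_stack([cx, cy]), czj) / _LN2
    return mi_joint - mi_x - mi_y


def build_tensor(emg, tasks, interaction: str) -> CouplingTensor:
    """Single-class convenience wrapper over :func:`build_tensors`."""
    if interaction not in INTERACTIONS:
        raise ValidationError(f"unknown interaction class {interaction!r}")
    return build_tensors(emg, tasks)[interaction]


def _pair_matrix(n: int, pairs, vec: np.ndarray) -> np.ndarray:
    m = np.zeros((n, n))
    for val, (i, j) in zip(vec, pairs):
        m[i, j] = val
        m[j, i] = val
    return m


def as_layers(tensor: CouplingTensor, orientation: str) -> NetworkLayerView:
    """Re-slice the tensor as symmetric adjacency matrices.

    spatial : muscle-wise couplings, one matrix per (timepoint pair, layer).
    temporal : timepoint-wise couplings, one matrix per (muscle pair, layer).
    """
    if orientation == "spatial":
        mats = np.zeros((len(tensor.time_pairs) * tensor.n_layers,
                         tensor.n_muscles, tensor.n_muscles))
        keys = []
        for qi in range(len(tensor.time_pairs)):
            for li in range(tensor.n_layers):
                mats[qi * tensor.n_layers + li] = _pair_matrix(
                    tensor.n_muscles, tensor.muscle_pairs, tensor.values[:, qi, li])
                keys.append((qi, li))
    elif orientation == "temporal":
        mats = np.zeros((len(tensor.muscle_pairs) * tensor.n_layers,
                         tensor.n_timepoints, tensor.n_timepoints))
        keys = []
        for pi in range(len(tensor.muscle_pairs)):
            for li in range(tensor.n_layers):
                mats[pi * tensor.n_layers + li] = _pair_matrix(
                    tensor.n_timepoints, tensor.time_pairs, tensor.values[pi, :, li])
                keys.append((pi, li))
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    return NetworkLayerView(orientation, mats, keys)


def tensor_from_layers(view: NetworkLayerView, template: CouplingTensor) -> CouplingTensor:
    """Inverse of :func:`as_layers`; round-trips losslessly."""
    values = np.zeros_like(template.values)
    if view.orientation == "spatial":
        for mat, (qi, li) in zip(view.matrices, view.keys):
            for pi, (i, j) in enumerate(template.muscle_pairs):
                values[pi, qi, li] = mat[i, j]
    elif view.orientation == "temporal":
        for mat, (pi, li) in zip(view.matrices, view.keys):
            for qi, (t1, t2) in enumerate(template.time_pairs):
                values[pi, qi, li] = mat[t1, t2]
    else:
        raise ValidationError(f"unknown orientation {view.orientation!r}")
    return template.copy_with(values)
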