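"""Copula-based information estimators for muscle-task couplings.

Muscle couplings are quantified with mutual information (MI) estimated
semi-parametrically through the Gaussian copula: each margin is rank-mapped
onto a standard normal, after which MI equals the negative entropy of the
empirical copula and can be computed from bias-corrected Gaussian entropies.
The estimator is invariant under strictly monotone transforms of each
margin, so EMG amplitude units and static nonlinearities are immaterial.

Task relevance of a muscle pair ``[mx, my]`` against a task variable ``tau``
is measured with co-information,

    I(mx; my; tau) = I([mx, my]; tau) - I(mx; tau) - I(my; tau),

whose sign separates net-redundant (negative: both muscles carry the same
task information) from net-synergistic (positive: task information emerges
only from the joint observation) couplings.  Task-irrelevant couplings are
the conditional MI I(mx; my | tau).

Entropies are computed in nats internally and converted to bits at the
interface.  Nonnegative quantities (MI, CMI) are clipped at zero; the
signed co-information is assembled from the *unclipped* component estimates
so that the additive identity above holds exactly per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import ndtri, psi
from scipy.stats import rankdata

from ._exceptions import DegenerateInputError, ValidationError

__all__ = [
    "InformationEstimate",
    "TaskVariable",
    "copula_normalize",
    "gaussian_entropy_bits",
    "mi_gc",
    "mi_mixed",
    "cmi",
    "co_information",
    "mi_plugin_discrete",
    "split_signed",
]

_LN2 = np.log(2.0)
#: minimum sample count for rank-based copula estimation
MIN_SAMPLES = 8


@dataclass(frozen=True)
class InformationEstimate:
    """An information quantity in bits with estimator provenance.

    ``value`` is nonnegative for MI/CMI and signed for co-information.
    ``components`` carries the unclipped component MIs of a co-information
    estimate so the additive identity can be audited per call.
    """

    value: float
    estimator: Literal["gcmi", "gaussian_mixture", "plugin_discrete"]
    kind: Literal["MI", "CMI", "coI"]
    components: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class TaskVariable:
    """A per-trial task parameter.

    discrete : one label per trial (e.g. reaching direction); requires at
        least two classes with at least two trials each.
    continuous : a real series per trial, aligned with the envelope time
        base, shape (n_trials, n_timepoints) (e.g. a kinematic marker).
    """

    kind: Literal["discrete", "continuous"]
    values: np.ndarray
    name: str = "tau"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.kind == "discrete":
            if self.values.ndim != 1:
                raise ValidationError("discrete task variable must be 1-D (one label per trial)")
            _, counts = np.unique(self.values, return_counts=True)
            if len(counts) < 2:
                raise ValidationError(f"task variable {self.name!r} needs >= 2 classes")
            if counts.min() < 2:
                raise ValidationError(f"task variable {self.name!r} has a class with < 2 trials")
        elif self.kind == "continuous":
            if self.values.ndim != 2:
                raise ValidationError(
                    "continuous task variable must be (n_trials, n_timepoints)"
                )
            if not np.all(np.isfinite(self.values)):
                raise ValidationError(f"task variable {self.name!r} contains non-finite values")
        else:
            raise ValidationError(f"unknown task-variable kind {self.kind!r}")


def _as_samples(x: np.ndarray, name: str = "input") -> np.ndarray:
    """Coerce to an (n, d) float array and validate."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValidationError(f"{name} must be a vector or (n, d) matrix")
    if np.isnan(x).any() or not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains NaN or infinite values")
    return x


def copula_normalize(samples, tie_policy: str = "average") -> np.ndarray:
    """Map samples onto standard-normal ranks (the empirical copula transform).

    Each column is ranked and mapped through the standard-normal quantile
    function as ``ndtri(r / (n + 1))``.  The output is invariant under any
    strictly monotone transform of the input, which is what makes the
    downstream MI estimates distribution-free over margins.

    Parameters
    ----------
    samples : array-like, shape (n,) or (n, d)
    tie_policy : rank method for tied values, passed to
        :func:`scipy.stats.rankdata` ("average" keeps the transform
        deterministic and permutation-invariant).
    """
    x = _as_samples(samples)
    n = x.shape[0]
    if n < MIN_SAMPLES:
        raise ValidationError(f"need >= {MIN_SAMPLES} samples for copula estimation, got {n}")
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        if np.ptp(col) == 0.0:
            raise DegenerateInputError("all-identical samples cannot be copula-normalised")
        r = rankdata(col, method=tie_policy)
        out[:, j] = ndtri(r / (n + 1.0))
    return out if np.asarray(samples).ndim > 1 else out[:, 0]


def _entropy_nats(x: np.ndarray) -> float:
    """Bias-corrected Gaussian entropy in nats for (n, d) samples."""
    n, d = x.shape
    if n <= d + 1:
        raise ValidationError(f"need n > d + 1 samples for a {d}-D entropy, got n={n}")
    xm = x - x.mean(axis=0)
    cov = xm.T @ xm / (n - 1)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise DegenerateInputError("singular covariance: entropy undefined")
    h = 0.5 * logdet + 0.5 * d * (np.log(2.0 * np.pi) + 1.0)
    # small-sample bias correction (psi-function terms)
    psiterms = psi((n - np.arange(1, d + 1)) / 2.0) / 2.0
    h += d * (np.log(n - 1.0) - _LN2) / 2.0 - psiterms.sum()
    return float(h)


def gaussian_entropy_bits(samples) -> float:
    """Bias-corrected Gaussian (differential) entropy in bits.

    Translation invariant; for an (n, d) sample the correction uses the
    psi-function small-sample terms, so repeated draws are unbiased for
    the true Gaussian entropy to O(1/n^2).
    """
    x = _as_samples(samples)
    return _entropy_nats(x) / _LN2


def _mi_gc_nats(cx: np.ndarray, cy: np.ndarray) -> float:
    """MI in nats between already copula-normalised blocks (unclipped)."""
    joint = np.column_stack([cx, cy])
    return _entropy_nats(cx) + _entropy_nats(cy) - _entropy_nats(joint)


def mi_gc(x, y) -> InformationEstimate:
    """Gaussian-copula MI between two (possibly multivariate) samples, in bits.

    Symmetric in its arguments; negative bias-corrected estimates are
    clipped at zero.
    """
    x = _as_samples(x, "x")
    y = _as_samples(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    cx = copula_normalize(x)
    cy = copula_normalize(y)
    value = max(0.0, _mi_gc_nats(cx, cy) / _LN2)
    return InformationEstimate(value, "gcmi", "MI")


def _class_indices(labels: np.ndarray):
    classes, inv = np.unique(labels, return_inverse=True)
    return classes, [np.flatnonzero(inv == k) for k in range(len(classes))]


def _mi_mixed_nats(cx: np.ndarray, labels: np.ndarray) -> float:
    """Gaussian-mixture MI in nats between copula-normalised x and labels."""
    n, d = cx.shape
    classes, idx = _class_indices(labels)
    h_total = _entropy_nats(cx)
    h_cond = 0.0
    for cls, ii in zip(classes, idx):
        if len(ii) < d + 2:
            raise DegenerateInputError(
                f"class {cls!r} has {len(ii)} trials; need >= {d + 2} for a {d}-D covariance"
            )
        h_cond += (len(ii) / n) * _entropy_nats(cx[ii])
    return h_total - h_cond


def mi_mixed(x, tau: TaskVariable) -> InformationEstimate:
    """MI between continuous muscle samples and a discrete task variable.

    Uses a class-conditional Gaussian model on the copula-normalised data:
    overall Gaussian entropy minus the class-weighted conditional entropies.
    Clipped at zero.
    """
    x = _as_samples(x, "x")
    if tau.kind != "discrete":
        raise ValidationError("mi_mixed requires a discrete task variable")
    labels = np.asarray(tau.values)
    if len(labels) != x.shape[0]:
        raise ValidationError("task labels not aligned with trials")
    cx = copula_normalize(x)
    value = max(0.0, _mi_mixed_nats(cx, labels) / _LN2)
    return InformationEstimate(value, "gaussian_mixture", "MI")


def _cmi_nats_discrete(x: np.ndarray, y: np.ndarray, labels: np.ndarray) -> float:
    """Sum_c p(c) I(x;y | tau=c) with class-wise copula renormalisation."""
    n = x.shape[0]
    d = max(x.shape[1], y.shape[1])
    classes, idx = _class_indices(labels)
    total = 0.0
    for cls, ii in zip(classes, idx):
        if len(ii) < max(MIN_SAMPLES, 2 * d + 2):
            raise DegenerateInputError(
                f"class {cls!r} has {len(ii)} trials; too few for conditional MI"
            )
        cx = copula_normalize(x[ii])
        cy = copula_normalize(y[ii])
        total += (len(ii) / n) * _mi_gc_nats(cx, cy)
    return total


def _cmi_nats_continuous(cx: np.ndarray, cy: np.ndarray, cz: np.ndarray) -> float:
    """Closed-form Gaussian conditional MI on copula-normalised samples."""
    hxz = _entropy_nats(np.column_stack([cx, cz]))
    hyz = _entropy_nats(np.column_stack([cy, cz]))
    hz = _entropy_nats(cz)
    hxyz = _entropy_nats(np.column_stack([cx, cy, cz]))
    return hxz + hyz - hz - hxyz


def cmi(x, y, tau: TaskVariable | np.ndarray) -> InformationEstimate:
    """Conditional MI I(x; y | tau) in bits — the task-irrelevant coupling.

    Discrete tau: class-weighted copula MI with within-class rank
    renormalisation (conditioning changes the margins).  Continuous tau
    (passed as an aligned per-trial sample array): parametric Gaussian
    conditional MI on the copula-normalised triple.  Clipped at zero;
    symmetric in x and y.
    """
    x = _as_samples(x, "x")
    y = _as_samples(y, "y")
    if x.shape[0] != y.shape[0]:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if isinstance(tau, TaskVariable) and tau.kind == "discrete":
        labels = np.asarray(tau.values)
        if len(labels) != x.shape[0]:
            raise ValidationError("task labels not aligned with trials")
        value = _cmi_nats_discrete(x, y, labels) / _LN2
        est = "gaussian_mixture"
    else:
        z = tau.values if isinstance(tau, TaskVariable) else tau
        z = _as_samples(z, "tau")
        if z.shape[0] != x.shape[0]:
            raise ValidationError("task samples not aligned with trials")
        cx, cy, cz = copula_normalize(x), copula_normalize(y), copula_normalize(z)
        value = _cmi_nats_continuous(cx, cy, cz) / _LN2
        est = "gcmi"
    return InformationEstimate(max(0.0, value), est, "CMI")


def co_information(x, y, tau: TaskVariable | np.ndarray, estimator: str = "gcmi") -> InformationEstimate:
    """Signed co-information I(x; y; tau) in bits.

    Computed as I([x, y]; tau) - I(x; tau) - I(y; tau) from *unclipped*
    component estimates, so the additive identity holds exactly per call
    (the components are recorded on the returned estimate).  Negative
    values are net task-redundant couplings; positive values net
    task-synergistic.

    estimator : "gcmi" / "gaussian_mixture" select the continuous pipeline
        (the mixture model is chosen automatically for discrete tau);
        "plugin_discrete" treats x, y and tau as finite-alphabet symbols
        and uses exact plugin MIs (the worked truth-table examples).
    """
    if estimator == "plugin_discrete":
        xs = np.asarray(x)
        ys = np.asarray(y)
        ts = np.asarray(tau.values if isinstance(tau, TaskVariable) else tau)
        mi_x = mi_plugin_discrete(xs, ts).value
        mi_y = mi_plugin_discrete(ys, ts).value
        joint = np.column_stack([xs, ys])
        mi_joint = mi_plugin_discrete(joint, ts).value
        est_name = "plugin_discrete"
    else:
        x = _as_samples(x, "x")
        y = _as_samples(y, "y")
        if isinstance(tau, TaskVariable) and tau.kind == "discrete":
            labels = np.asarray(tau.values)
            cx = copula_normalize(x)
            cy = copula_normalize(y)
            cj = np.column_stack([cx, cy])
            mi_x = _mi_mixed_nats(cx, labels) / _LN2
            mi_y = _mi_mixed_nats(cy, labels) / _LN2
            mi_joint = _mi_mixed_nats(cj, labels) / _LN2
            est_name = "gaussian_mixture"
        else:
            z = tau.values if isinstance(tau, TaskVariable) else tau
            z = _as_samples(z, "tau")
            cx, cy, cz = copula_normalize(x), copula_normalize(y), copula_normalize(z)
            mi_x = _mi_gc_nats(cx, cz) / _LN2
            mi_y = _mi_gc_nats(cy, cz) / _LN2
            mi_joint = _mi_gc_nats(np.column_stack([cx, cy]), cz) / _LN2
            est_name = "gcmi"
    value = mi_joint - mi_x - mi_y
    return InformationEstimate(
        value,
        est_name,
        "coI",
        components={"mi_x": mi_x, "mi_y": mi_y, "mi_joint": mi_joint},
    )


def _discrete_codes(x: np.ndarray) -> np.ndarray:
    """Collapse a 1-D or (n, d) symbol array to integer codes per row."""
    x = np.asarray(x)
    if x.ndim == 1:
        x = x[:, None]
    _, codes = np.unique(x, axis=0, return_inverse=True)
    return codes.ravel()


def mi_plugin_discrete(x, y) -> InformationEstimate:
    """Exact plugin MI in bits from empirical joint frequencies.

    ``x`` may be a vector or an (n, d) matrix whose rows encode a joint
    symbol (e.g. the pair [mx, my] observed together).
    """
    cx = _discrete_codes(x)
    cy = _discrete_codes(y)
    if cx.size == 0:
        raise ValidationError("empty input")
    if cx.size != cy.size:
        raise ValidationError("length mismatch")
    n = cx.size
    joint = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(joint, (cx, cy), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    value = float(np.sum(pxy[mask] * np.log2(pxy[mask] / (px @ py)[mask])))
    return InformationEstimate(max(0.0, value), "plugin_discrete", "MI")


def split_signed(coi_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Parse a signed symmetric co-information matrix into rectified halves.

    Returns ``(redundant, synergistic)`` where ``redundant = max(0, -coI)``
    and ``synergistic = max(0, +coI)``; their difference reconstructs
    ``-coI`` exactly.
    """
    m = np.asarray(coi_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=0, rtol=0):
        raise ValidationError("co-information matrix must be exactly symmetric")
    return np.maximum(0.0, -m), np.maximum(0.0, m)
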