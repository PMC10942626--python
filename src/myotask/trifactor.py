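"""Sample-based non-negative matrix tri-factorisation (sNM3F) and a
non-negative CP comparator.

The sparsified coupling tensor A (muscle pairs x timepoint pairs x layers)
is decomposed as

    A[k, t, l]  ~=  sum_ij  S[l, i, j] * W[i, t] * V[j, k]

with shared nonnegative temporal factors W (rows are timepoint-pair
profiles), shared nonnegative spatial factors V (rows are muscle-pair
networks), and layer-specific nonnegative coefficients S.  The coupling
through S is all-to-all: any spatial factor may combine with any temporal
factor, with a participant- and task-specific weight.  S is a scaling of
information overlap, not variance accounted for.

Fitting uses multiplicative updates (monotone non-increasing objective)
with an optional orthogonality-encouraging penalty on the factor Gram
matrices, random nonnegative initialisation, and best-of-restarts.  An
optional binary mask excludes entries from the objective, which is how the
robustness protocol "removes" columns without changing factor shapes.

The CP decomposition (one-to-one factor pairing, used only as a
generalisability comparator) is fitted with masked multiplicative ALS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError

__all__ = [
    "FitOptions",
    "SpaceTimeDecomposition",
    "CPDecomposition",
    "snm3f_fit",
    "cp_fit",
    "reconstruct",
]

_EPS = 1e-12


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 10
    seed: int = 0
    orthogonality_weight_v: float = 1e-4
    orthogonality_weight_w: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.tol <= 0:
            raise ValidationError("require max_iter >= 1 and tol > 0")


@dataclass
class SpaceTimeDecomposition:
    """Factors of the tri-factorisation A ~= sum_ij S_lij W_i V_j."""

    W: np.ndarray  # (temporal_rank, n_time_pairs)
    V: np.ndarray  # (spatial_rank, n_muscle_pairs)
    S: np.ndarray  # (n_layers, temporal_rank, spatial_rank)
    residual: float
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def spatial_rank(self) -> int:
        return self.V.shape[0]

    @property
    def temporal_rank(self) -> int:
        return self.W.shape[0]

    @property
    def spatial_factors(self) -> np.ndarray:
        """Spatial factors as columns (n_muscle_pairs, spatial_rank)."""
        return self.V.T

    @property
    def temporal_factors(self) -> np.ndarray:
        """Temporal factors as columns (n_time_pairs, temporal_rank)."""
        return self.W.T


@dataclass
class CPDecomposition:
    """Non-negative CP factors with one-to-one component pairing."""

    spatial: np.ndarray   # (n_muscle_pairs, rank)
    temporal: np.ndarray  # (n_time_pairs, rank)
    layer: np.ndarray     # (n_layers, rank)
    residual: float
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def spatial_factors(self) -> np.ndarray:
        return self.spatial

    @property
    def temporal_factors(self) -> np.ndarray:
        return self.temporal


def _coerce_tensor(a) -> np.ndarray:
    if hasattr(a, "values") and hasattr(a, "mask"):  # SparseCoupling
        a = a.values
    elif hasattr(a, "values") and not isinstance(a, np.ndarray):  # CouplingTensor
        a = a.values
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValidationError("input tensor must be (muscle pairs, time pairs, layers)")
    if (a < 0).any():
        raise ValidationError("input tensor must be nonnegative")
    return a


def reconstruct(dec: SpaceTimeDecomposition) -> np.ndarray:
    """Tensor implied by the factors: sum over factor pairs of S * (W x V)."""
    return np.einsum("lij,it,jk->ktl", dec.S, dec.W, dec.V)


def _snm3f_once(a, mask, r_t, r_s, opts: FitOptions, rng) -> SpaceTimeDecomposition:
    k, t, n_layers = a.shape
    w = rng.uniform(0.1, 1.0, size=(r_t, t))
    v = rng.uniform(0.1, 1.0, size=(r_s, k))
    s = rng.uniform(0.1, 1.0, size=(n_layers, r_t, r_s))
    lam_v = opts.orthogonality_weight_v
    lam_w = opts.orthogonality_weight_w
    am = a * mask
    norm_a = np.linalg.norm(am)

    def model():
        return np.einsum("lij,it,jk->ktl", s, w, v)

    def objective(m):
        resid = np.linalg.norm((a - m) * mask) ** 2
        pen = 0.0
        if lam_v:
            pen += lam_v * np.linalg.norm(v @ v.T - np.eye(r_s)) ** 2
        if lam_w:
            pen += lam_w * np.linalg.norm(w @ w.T - np.eye(r_t)) ** 2
        return resid + pen

    history = []
    m = model()
    prev = objective(m)
    history.append(prev)
    for _ in range(opts.max_iter):
        mm = m * mask
        # W update
        sv = np.einsum("lij,jk->lik", s, v)                  # (L, r_t, K)
        num = np.einsum("lik,ktl->it", sv, am)
        den = np.einsum("lik,ktl->it", sv, mm) + _EPS
        if lam_w:
            num = num + 4 * lam_w * w
            den = den + 4 * lam_w * (w @ w.T @ w)
        w *= num / den
        m = model()
        mm = m * mask
        # V update
        sw = np.einsum("lij,it->ljt", s, w)                  # (L, r_s, T)
        num = np.einsum("ljt,ktl->jk", sw, am)
        den = np.einsum("ljt,ktl->jk", sw, mm) + _EPS
        if lam_v:
            num = num + 4 * lam_v * v
            den = den + 4 * lam_v * (v @ v.T @ v)
        v *= num / den
        m = model()
        mm = m * mask
        # S update
        num = np.einsum("it,ktl,jk->lij", w, am, v)
        den = np.einsum("it,ktl,jk->lij", w, mm, v) + _EPS
        s *= num / den
        m = model()
        cur = objective(m)
        history.append(cur)
        if prev > 0 and abs(prev - cur) / max(prev, _EPS) < opts.tol:
            prev = cur
            break
        prev = cur
    else:
        warnings.warn(
            f"sNM3F did not converge in {opts.max_iter} iterations "
            f"(final objective {prev:.3e})", stacklevel=3)

    resid = np.linalg.norm((a - model()) * mask)
    rel = resid / norm_a if norm_a > 0 else resid
    return SpaceTimeDecomposition(w, v, s, float(rel), np.asarray(history))


def snm3f_fit(a, rank, opts: FitOptions = FitOptions(), mask=None) -> SpaceTimeDecomposition:
    """Fit the tri-factorisation at the given (spatial, temporal) model rank.

    rank : a :class:`~myotask.modularity.ModelRank` or ``(spatial, temporal)``
        tuple.  ``mask`` (same shape as the tensor, optional) restricts the
        objective to unmasked entries.
    """
    a = _coerce_tensor(a)
    r_s, r_t = (rank.spatial, rank.temporal) if hasattr(rank, "spatial") else tuple(rank)
    k, t, n_layers = a.shape
    if r_s < 1 or r_t < 1 or r_s > k or r_t > t:
        raise ValidationError(f"rank ({r_s}, {r_t}) out of range for tensor {a.shape}")
    mask = np.ones_like(a) if mask is None else np.asarray(mask, dtype=float)
    if mask.shape != a.shape:
        raise ValidationError("mask shape must match the tensor")
    rng = np.random.default_rng(opts.seed)
    best = None
    for _ in range(max(1, opts.n_restarts)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = _snm3f_once(a, mask, r_t, r_s, opts, rng)
        if best is None or dec.residual < best.residual:
            best = dec
    return best


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    r = b.shape[1]
    return (b[:, None, :] * c[None, :, :]).reshape(-1, r)


def cp_fit(a, rank: int, opts: FitOptions = FitOptions(), mask=None) -> CPDecomposition:
    """Masked non-negative CP (canonical polyadic) decomposition.

    One-to-one pairing: component r couples spatial pattern r exclusively
    with temporal pattern r.  Used as the generalisability comparator.
    """
    a = _coerce_tensor(a)
    if rank < 1 or rank > min(a.shape):
        raise ValidationError(f"CP rank {rank} out of range for tensor {a.shape}")
    mask = np.ones_like(a) if mask is None else np.asarray(mask, dtype=float)
    rng = np.random.default_rng(opts.seed)
    norm_a = np.linalg.norm(a * mask)

    best = None
    for _ in range(max(1, opts.n_restarts)):
        factors = [rng.uniform(0.1, 1.0, size=(dim, rank)) for dim in a.shape]
        history = []
        prev = None
        for _ in range(opts.max_iter):
            model = np.einsum("kr,tr,lr->ktl", *factors)
            for mode in range(3):
                others = [factors[m] for m in range(3) if m != mode]
                kr = _khatri_rao(others[0], others[1])
                num = _unfold(a * mask, mode) @ kr
                den = _unfold(model * mask, mode) @ kr + _EPS
                factors[mode] = factors[mode] * num / den
                model = np.einsum("kr,tr,lr->ktl", *factors)
            cur = np.linalg.norm((a - model) * mask) ** 2
            history.append(cur)
            if prev is not None and prev > 0 and abs(prev - cur) / prev < opts.tol:
                break
            prev = cur
        resid = np.sqrt(history[-1]) / norm_a if norm_a > 0 else np.sqrt(history[-1])
        dec = CPDecomposition(factors[0], factors[1], factors[2], float(resid),
                              np.asarray(history))
        if best is None or dec.residual < best.residual:
            best = dec
    return best
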