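"""Generalisability of extracted space-time muscle networks.

Representations extracted from the full coupling tensor are compared with
representations re-extracted after removing part of the input: one
participant or task variable at a time (leave-n-out), or randomly sized
subsets of randomly selected column vectors (random ablation, 50
iterations by default).  Factor order is arbitrary in NMF-family models,
so factors are first matched by a greedy maximum-correlation assignment,
then Pearson-correlated pairwise; correlations are summarised through
Fisher's Z (atanh -> mean/sd -> tanh).  Spatial and temporal factors are
compared separately; the layer coefficients S are excluded (the objects
of interest are the networks).

Because the back-transformed sd can exceed the correlation bound, the
Z-scale sd is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .trifactor import FitOptions, cp_fit, snm3f_fit

__all__ = [
    "SimilarityReport",
    "match_and_correlate",
    "leave_n_out",
    "random_ablation",
    "fisher_summary",
]


@dataclass
class SimilarityReport:
    """Per-comparison matched-factor correlations plus Fisher-Z summaries."""

    protocol: str
    rows: list = field(default_factory=list)  # dicts: unit, orientation, factor, r
    seed: int = 0
    n_iterations: int = 0

    def correlations(self, orientation: str | None = None) -> np.ndarray:
        rs = [row["r"] for row in self.rows
              if orientation is None or row["orientation"] == orientation]
        return np.asarray(rs, dtype=float)

    def summary(self, orientation: str | None = None) -> dict:
        rs = self.correlations(orientation)
        if rs.size == 0:
            raise ValidationError("no comparisons recorded")
        mean_r, sd_r, z_sd = fisher_summary(rs, return_z_sd=True)
        return {"mean_r": mean_r, "sd_r": sd_r, "z_sd": z_sd, "n": int(rs.size)}

    def to_records(self) -> list:
        return [dict(row) for row in self.rows]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _greedy_match(ref_cols: np.ndarray, test_cols: np.ndarray) -> list:
    """Each reference factor to its best unmatched test factor, by Pearson r."""
    r_ref, r_test = ref_cols.shape[1], test_cols.shape[1]
    corr = np.array([[_pearson(ref_cols[:, i], test_cols[:, j])
                      for j in range(r_test)] for i in range(r_ref)])
    pairs = []
    used_ref, used_test = set(), set()
    flat = sorted(((corr[i, j], i, j) for i in range(r_ref) for j in range(r_test)),
                  key=lambda t: (-t[0], t[1], t[2]))
    for r, i, j in flat:
        if i in used_ref or j in used_test:
            continue
        pairs.append((i, j, r))
        used_ref.add(i)
        used_test.add(j)
    pairs.sort(key=lambda t: t[0])
    return pairs


def match_and_correlate(ref, test) -> dict:
    """Matched-factor Pearson correlations between two decompositions.

    Works for any pair of objects exposing ``spatial_factors`` and
    ``temporal_factors`` as (dimension, rank) arrays with equal shapes.
    Returns {"spatial": r per reference factor, "temporal": ...}.
    """
    out = {}
    for orientation in ("spatial", "temporal"):
        rc = getattr(ref, f"{orientation}_factors")
        tc = getattr(test, f"{orientation}_factors")
        if rc.shape != tc.shape:
            raise ValidationError(
                f"{orientation} rank/dimension mismatch: {rc.shape} vs {tc.shape}")
        out[orientation] = np.asarray([r for _, _, r in _greedy_match(rc, tc)])
    return out


def fisher_summary(rs, return_z_sd: bool = False):
    """tanh(mean(atanh(r))), tanh(sd(atanh(r))) over a correlation list."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValidationError("empty correlation list")
    limit = 1.0 - 1e-10
    if (np.abs(rs) >= 1.0).any():
        warnings.warn("correlations of +/-1 clipped for the Z-transform", stacklevel=2)
        rs = np.clip(rs, -limit, limit)
    z = np.arctanh(rs)
    mean_r = float(np.tanh(z.mean()))
    z_sd = float(z.std())
    sd_r = float(np.tanh(z_sd))
    if return_z_sd:
        return mean_r, sd_r, z_sd
    return mean_r, sd_r


def _fit(tensor_values, rank, opts, mask=None, method: str = "snm3f"):
    if method == "snm3f":
        return snm3f_fit(tensor_values, rank, opts, mask=mask)
    if method == "cp":
        r_s, r_t = (rank.spatial, rank.temporal) if hasattr(rank, "spatial") else tuple(rank)
        return cp_fit(tensor_values, max(r_s, r_t), opts, mask=mask)
    raise ValidationError(f"unknown method {method!r}")


def leave_n_out(tensor, rank, axis: str = "participant",
                opts: FitOptions = FitOptions(), seed: int = 0,
                method: str = "snm3f", reference=None) -> SimilarityReport:
    """Hold out one participant or task variable at a time and compare.

    ``tensor`` is a :class:`~myotask.coupling.CouplingTensor` (or a
    SparseCoupling with its parent) whose layer labels identify (task,
    participant); the held-out unit's layers are dropped, the model is
    re-fitted at the same rank, and factors are matched and correlated
    against the full-data reference.
    """
    if hasattr(tensor, "tensor") and tensor.tensor is not None:
        tensor = tensor.tensor.copy_with(tensor.values)
    if axis not in ("participant", "task"):
        raise ValidationError("axis must be 'participant' or 'task'")
    labels = [lab[1] if axis == "participant" else lab[0] for lab in tensor.layer_labels]
    units = sorted(set(labels), key=str)
    if len(units) < 2:
        raise ValidationError(f"need >= 2 {axis}s for leave-one-out")

    opts_ref = opts
    if reference is None:
        reference = _fit(tensor.values, rank, opts_ref, method=method)
    report = SimilarityReport(protocol=f"leave_one_{axis}", seed=seed)
    for unit in units:
        keep = [li for li, lab in enumerate(labels) if lab != unit]
        sub = tensor.values[:, :, keep]
        dec = _fit(sub, rank, opts, method=method)
        rs = match_and_correlate(reference, dec)
        for orientation in ("spatial", "temporal"):
            for fi, r in enumerate(rs[orientation]):
                report.rows.append({"unit": unit, "orientation": orientation,
                                    "factor": fi, "r": float(r)})
    report.n_iterations = len(units)
    return report


def random_ablation(tensor, rank, n_iterations: int = 50, seed: int = 0,
                    opts: FitOptions = FitOptions(), method: str = "snm3f",
                    reference=None, ablation_fraction=None) -> SimilarityReport:
    """Randomly ablate column vectors of the input and compare re-extractions.

    Per iteration a uniformly random number (1 .. n_columns - 1, unless
    ``ablation_fraction`` overrides it) of the (timepoint-pair, layer)
    column vectors is excluded from the fitting objective via a mask; the
    re-extracted factors are matched and correlated against the full-data
    reference.  Deterministic given the seed.
    """
    values = tensor.values if hasattr(tensor, "values") else np.asarray(tensor, float)
    if values.ndim != 3:
        raise ValidationError("tensor must be 3-D")
    if n_iterations < 1:
        raise ValidationError("need n_iterations >= 1")
    k, t, n_layers = values.shape
    n_cols = t * n_layers
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = _fit(values, rank, opts, method=method)
    report = SimilarityReport(protocol="random_ablation", seed=seed,
                              n_iterations=n_iterations)
    for it in range(n_iterations):
        if ablation_fraction is not None:
            n_drop = int(round(ablation_fraction * n_cols))
        else:
            n_drop = int(rng.integers(1, n_cols))
        mask = np.ones_like(values)
        if n_drop > 0:
            cols = rng.choice(n_cols, size=n_drop, replace=False)
            ti, li = np.unravel_index(cols, (t, n_layers))
            mask[:, ti, li] = 0.0
        dec = _fit(values, rank, opts, mask=mask, method=method)
        rs = match_and_correlate(reference, dec)
        for orientation in ("spatial", "temporal"):
            for fi, r in enumerate(rs[orientation]):
                report.rows.append({"unit": it, "orientation": orientation,
                                    "factor": fi, "r": float(r)})
    return report
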