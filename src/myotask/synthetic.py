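"""Trial-structured synthetic EMG with planted task-space couplings.

The generator emulates the statistical structure of the three interaction
classes so every pipeline stage can be validated without recorded data:

redundant : both muscles are driven by the same task-dependent latent
    (plus independent noise), so each alone predicts the task and their
    co-information is negative.
synergistic : the joint observation carries more task information than
    the marginals — parity coding for a discrete task (one muscle carries
    a random bit, the other the bit XOR the class, so neither alone is
    predictive), complementary-component coding for a continuous task
    (the task tracks the *sum* of two independent latents carried by
    different muscles, so their co-information is net positive).
irrelevant : the muscles share a latent that is independent of the task,
    surviving conditioning on the task variable.

Envelope nonnegativity is enforced with a softplus of the latent sum; the
downstream estimators are rank-based, so the softplus (strictly monotone)
does not alter any information quantity.  The worked four-observation
truth tables for pure redundancy and pure synergy are provided by
:func:`truth_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import ValidationError
from .information import TaskVariable
from .preprocessing import ProcessedEMG

__all__ = [
    "PlantedCoupling",
    "SyntheticSpec",
    "generate",
    "truth_tables",
    "score_recovery",
]


@dataclass(frozen=True)
class PlantedCoupling:
    """One planted muscle-pair coupling over a timepoint range.

    Plants sharing a ``group`` name share one latent, so a group forms a
    coupled module whose members are mutually dependent; plants in
    different groups get independent latents (for a discrete task each
    group draws its own class-effect vector, so groups carry distinct
    task information and are not coupled to each other).  With
    ``group=None`` a redundant plant is driven by the global centred
    class code, and synergistic/irrelevant plants draw per-plant latents.
    """

    muscles: tuple       # (i, j), i != j
    time_range: tuple    # (t_start, t_stop) half-open
    kind: str            # redundant | synergistic | irrelevant
    strength: float = 1.0
    group: str | None = None


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a single-arm reaching study: 7 participants, 640
    trials each, 9 muscles, 50-step envelopes, a 2-class discrete task,
    unit noise.
    """

    n_participants: int = 7
    n_trials: int = 640
    n_muscles: int = 9
    n_timepoints: int = 50
    planted: list = field(default_factory=list)
    task_kind: str = "discrete"
    n_classes: int = 2
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen = {}
        for p in self.planted:
            i, j = p.muscles
            if i == j or not (0 <= i < self.n_muscles and 0 <= j < self.n_muscles):
                raise ValidationError(f"planted pair {p.muscles} out of bounds")
            t0, t1 = p.time_range
            if not (0 <= t0 < t1 <= self.n_timepoints):
                raise ValidationError(f"planted time range {p.time_range} out of bounds")
            if p.strength < 0:
                raise ValidationError("planted strength must be >= 0")
            key = tuple(sorted(p.muscles))
            if key in seen and seen[key] != p.kind:
                raise ValidationError(f"contradictory classes planted on pair {key}")
            seen[key] = p.kind
        if self.task_kind not in ("discrete", "continuous"):
            raise ValidationError(f"unknown task kind {self.task_kind!r}")
        if self.task_kind == "discrete" and self.n_classes < 2:
            raise ValidationError("discrete task needs >= 2 classes")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate(spec: SyntheticSpec):
    """Generate (list of ProcessedEMG, [TaskVariable], ground_truth).

    Deterministic: the same spec (seed included) yields byte-identical
    output.  ``ground_truth`` lists the planted entries in muscle-pair /
    timepoint coordinates for recovery scoring.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, t = spec.n_trials, spec.n_muscles, spec.n_timepoints
    emg_out = []

    if spec.task_kind == "discrete":
        labels = np.tile(np.arange(spec.n_classes), n // spec.n_classes + 1)[:n]
        tau = TaskVariable("discrete", labels, name="condition")
        class_effect = labels - labels.mean()  # centred, equally spaced
    else:
        tau = None  # assembled per participant below (shared across them)

    for _p in range(spec.n_participants):
        raw = spec.noise_sd * rng.standard_normal((n, m, t))
        if spec.task_kind == "continuous":
            tau_p = spec.noise_sd * rng.standard_normal((n, t))
        cache: dict = {}
        tau_added: dict = {}

        def latents(pid: int, pc: PlantedCoupling):
            """Latent draws shared within a plant group, fresh per plant otherwise."""
            key = (pc.kind, pc.group if pc.group is not None else f"_plant{pid}")
            if key not in cache:
                if spec.task_kind == "discrete":
                    if pc.kind == "redundant":
                        if pc.group is None:
                            effect = class_effect
                        else:
                            # groups carry independent task dimensions:
                            # class-effect vectors are orthogonalised
                            # against earlier groups' and centred
                            e = rng.standard_normal(spec.n_classes)
                            basis = cache.setdefault("_effect_basis", [])
                            e -= e.mean()
                            for b in basis:
                                e -= (e @ b) * b
                            norm = np.linalg.norm(e)
                            if norm < 1e-9:
                                raise ValidationError(
                                    "more redundant groups than independent class dimensions")
                            e /= norm
                            basis.append(e.copy())
                            effect = e[labels] * np.sqrt(spec.n_classes)
                        cache[key] = (effect,)
                    elif pc.kind == "synergistic":
                        bit = rng.integers(0, 2, size=n) * 2 - 1
                        cache[key] = (bit, bit * (2 * (labels % 2) - 1))
                    else:
                        cache[key] = (rng.standard_normal(n),)
                else:
                    if pc.kind == "synergistic":
                        cache[key] = (rng.standard_normal((n, t)),
                                      rng.standard_normal((n, t)))
                    else:
                        cache[key] = (rng.standard_normal((n, t)),)
            return key, cache[key]

        for pid, pc in enumerate(spec.planted):
            i, j = pc.muscles
            t0, t1 = pc.time_range
            span = slice(t0, t1)
            key, lat = latents(pid, pc)
            if spec.task_kind == "discrete":
                if pc.kind == "synergistic":
                    bit, parity = lat
                    raw[:, i, span] += pc.strength * bit[:, None]
                    raw[:, j, span] += pc.strength * parity[:, None]
                else:
                    raw[:, i, span] += pc.strength * lat[0][:, None]
                    raw[:, j, span] += pc.strength * lat[0][:, None]
            else:
                # continuous: the task variable receives each group's
                # contribution once per timepoint, however many plants share it
                fresh = ~tau_added.setdefault(key, np.zeros(t, dtype=bool))[span]
                if pc.kind == "synergistic":
                    # complementary components: each muscle carries a
                    # different additive part of the task signal, so the
                    # joint observation is worth more than the marginals
                    a, b = lat
                    raw[:, i, span] += pc.strength * a[:, span]
                    raw[:, j, span] += pc.strength * b[:, span]
                    tau_p[:, span][:, fresh] += (a + b)[:, span][:, fresh]
                elif pc.kind == "redundant":
                    raw[:, i, span] += pc.strength * lat[0][:, span]
                    raw[:, j, span] += pc.strength * lat[0][:, span]
                    tau_p[:, span][:, fresh] += lat[0][:, span][:, fresh]
                else:
                    raw[:, i, span] += pc.strength * lat[0][:, span]
                    raw[:, j, span] += pc.strength * lat[0][:, span]
                tau_added[key][span] = True
        env = _softplus(raw)
        emg_out.append(ProcessedEMG(env, provenance=["synthetic"]))
        if spec.task_kind == "continuous" and tau is None:
            tau = TaskVariable("continuous", tau_p, name="kinematic")

    ground_truth = {
        "planted": [
            {"muscles": list(pc.muscles), "time_range": list(pc.time_range),
             "kind": pc.kind, "strength": pc.strength}
            for pc in spec.planted
        ],
        "task_kind": spec.task_kind,
        "seed": spec.seed,
    }
    return emg_out, [tau], ground_truth


def truth_tables():
    """The four-observation pure-redundancy and pure-synergy truth tables.

    redundancy : mx on exactly when my is off, and the task is L exactly
        when mx is on — either muscle alone yields the full task bit.
    synergy : all four joint on/off states, task L exactly when the
        muscles agree — neither muscle alone is informative, together
        they yield the full bit.
    """
    redundancy = {
        "mx": np.array([1, 1, 0, 0]),
        "my": np.array([0, 0, 1, 1]),
        "tau": np.array(["L", "L", "R", "R"]),
    }
    synergy = {
        "mx": np.array([1, 0, 1, 0]),
        "my": np.array([1, 0, 0, 1]),
        "tau": np.array(["L", "L", "R", "R"]),
    }
    return redundancy, synergy


def planted_entry_set(ground_truth: dict, muscle_pairs, time_pairs, kind: str) -> set:
    """(muscle-pair index, timepoint-pair index) entries implied by the plant."""
    mp_index = {tuple(sorted(p)): k for k, p in enumerate(muscle_pairs)}
    out = set()
    for pc in ground_truth["planted"]:
        if pc["kind"] != kind:
            continue
        key = tuple(sorted(pc["muscles"]))
        if key not in mp_index:
            continue
        t0, t1 = pc["time_range"]
        for qi, (ta, tb) in enumerate(time_pairs):
            if t0 <= ta < t1 and t0 <= tb < t1:
                out.add((mp_index[key], qi))
    return out


def score_recovery(ground_truth: dict, sparse, kind: str) -> dict:
    """Precision/recall of planted couplings among retained tensor entries.

    An entry counts as retained if its dual-domain mask is true in any
    layer.  With an empty retained set, recall is 0 and precision is
    reported as 1.0 (vacuously no false positives).
    """
    tensor = sparse.tensor
    retained = {(pi, qi)
                for pi in range(sparse.mask.shape[0])
                for qi in range(sparse.mask.shape[1])
                if sparse.mask[pi, qi, :].any()}
    planted = planted_entry_set(ground_truth, tensor.muscle_pairs, tensor.time_pairs, kind)
    tp = len(retained & planted)
    precision = tp / len(retained) if retained else 1.0
    recall = tp / len(planted) if planted else 1.0
    return {"precision": precision, "recall": recall,
            "n_retained": len(retained), "n_planted": len(planted)}
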