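"""Declarative pipeline configuration.

Defaults are the framework's published operating point: 20 Hz low-pass
cut-off, 1000-sample time base integrated over 20-sample windows,
resolution parameters gamma = omega = 1 (classical modularity), 100 null
networks for percolation, 50 random-ablation iterations.  A single global
seed deterministically derives every stage seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from ._exceptions import ValidationError

__all__ = ["PipelineConfig", "stage_seed"]

_STAGES = ("synthetic", "preprocess", "couple", "sparsify", "rank",
           "decompose", "analyze", "robustness")


@dataclass
class PipelineConfig:
    # preprocessing
    cutoff_hz: float = 20.0
    n_samples: int = 1000
    window: int = 20
    filter_order: int = 4
    # percolation
    n_random: int = 100
    null_statistic: str = "mean"
    null_percentile: float = 5.0
    # rank selection
    gamma: float = 1.0
    omega: float = 1.0
    detection_repeats: int = 50
    # factorisation
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 10
    orthogonality_weight_v: float = 1e-4
    orthogonality_weight_w: float = 0.0
    # robustness
    ablation_iterations: int = 50
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples % self.window:
            raise ValidationError("window must divide the normalised length")
        if self.null_statistic not in ("mean", "percentile"):
            raise ValidationError("null_statistic must be 'mean' or 'percentile'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def stage_seed(config: PipelineConfig, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    if stage not in _STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(_STAGES))
    return int(children[_STAGES.index(stage)].generate_state(1)[0] % (2**31))
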