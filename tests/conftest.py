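"""Shared fixtures: small planted datasets generated at test time."""

from itertools import combinations

import numpy as np
import pytest

from myotask.coupling import build_tensors
from myotask.percolation import sparsify_tensor
from myotask.synthetic import PlantedCoupling, SyntheticSpec, generate


def rank32_spec(seed: int = 0, participants: int = 2, trials: int = 800,
                strength: float = 2.0) -> SyntheticSpec:
    """Three redundant muscle groups active in two envelope windows.

    Groups carry orthogonal dimensions of an 8-class task, so the coupling
    tensor has three spatial and two temporal modules by construction.
    """
    plants = []
    for gi, gm in enumerate([(0, 1, 2), (3, 4, 5), (6, 7, 8)]):
        for wname, wr in {"A": (0, 5), "B": (5, 10)}.items():
            for i, j in combinations(gm, 2):
                plants.append(PlantedCoupling((i, j), wr, "redundant", strength,
                                              group=f"g{gi}{wname}"))
    return SyntheticSpec(n_participants=participants, n_trials=trials, n_muscles=9,
                         n_timepoints=10, planted=plants, task_kind="discrete",
                         n_classes=8, seed=seed)


@pytest.fixture(scope="session")
def rank32_sparse_tensor():
    """Sparsified redundant-class tensor of the rank-(3, 2) dataset."""
    emg, tasks, truth = generate(rank32_spec(seed=0, participants=2, trials=800))
    tensors = build_tensors(emg, tasks)
    sp = sparsify_tensor(tensors["redundant"], n_random=200, seed=0)
    return tensors["redundant"], sp, truth


@pytest.fixture(scope="session")
def small_planted_dataset():
    """One participant, 6 muscles: disjoint redundant, synergistic and
    irrelevant planted pairs against a 2-class task."""
    spec = SyntheticSpec(
        n_participants=1, n_trials=1500, n_muscles=6, n_timepoints=4,
        planted=[
            PlantedCoupling((0, 1), (0, 4), "redundant", 3.0),
            PlantedCoupling((2, 3), (0, 4), "synergistic", 3.0),
            PlantedCoupling((4, 5), (0, 4), "irrelevant", 3.0),
        ],
        task_kind="discrete", n_classes=2, seed=42)
    emg, tasks, truth = generate(spec)
    return emg, tasks, truth


@pytest.fixture(scope="session")
def small_tensors(small_planted_dataset):
    emg, tasks, _ = small_planted_dataset
    return build_tensors(emg, tasks)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
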