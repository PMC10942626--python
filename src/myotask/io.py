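"""Readers and writers for the pipeline's typed objects.

Trial tensors travel as a long-format CSV plus a JSON manifest (muscle
names, shape, trial-to-label mapping); coupling tensors and decompositions
as compressed ``.npz`` containers with axis-label metadata; networks as
GraphML; reports as JSON.  All text is UTF-8 with LF endings and floats
are written with 17 significant digits so round trips are exact.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .coupling import CouplingTensor
from .information import TaskVariable
from .preprocessing import ProcessedEMG
from .trifactor import SpaceTimeDecomposition

__all__ = [
    "write_emg", "read_emg",
    "write_task", "read_task",
    "write_tensor", "read_tensor",
    "write_decomposition", "read_decomposition",
    "write_network_graphml", "write_json", "read_json",
]

_FLOAT_FMT = "%.17g"


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n",
                          encoding="utf-8", newline="\n")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_emg(directory, emg: ProcessedEMG, name: str = "emg") -> None:
    """Envelope tensor -> <name>.csv (trial, muscle, timepoint, value) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, m, t = emg.envelope.shape
    trial, muscle, tp = np.meshgrid(np.arange(n), np.arange(m), np.arange(t),
                                    indexing="ij")
    df = pd.DataFrame({
        "trial": trial.ravel(), "muscle": muscle.ravel(),
        "timepoint": tp.ravel(), "value": emg.envelope.ravel(),
    })
    df.to_csv(directory / f"{name}.csv", index=False, float_format=_FLOAT_FMT,
              lineterminator="\n")
    write_json(directory / f"{name}.manifest.json", {
        "n_trials": n, "n_muscles": m, "n_timepoints": t,
        "muscles": list(emg.muscle_names), "provenance": list(emg.provenance),
    })


def read_emg(directory, name: str = "emg") -> ProcessedEMG:
    directory = Path(directory)
    manifest = read_json(directory / f"{name}.manifest.json")
    df = pd.read_csv(directory / f"{name}.csv")
    n, m, t = manifest["n_trials"], manifest["n_muscles"], manifest["n_timepoints"]
    if len(manifest["muscles"]) not in (0, m):
        raise ValidationError(
            f"manifest lists {len(manifest['muscles'])} muscles but declares {m}")
    if len(df) != n * m * t:
        raise ValidationError(f"CSV has {len(df)} rows, manifest implies {n * m * t}")
    env = np.zeros((n, m, t))
    env[df["trial"], df["muscle"], df["timepoint"]] = df["value"]
    if n == 1:
        warnings.warn("single-trial dataset: estimators will reject it downstream",
                      stacklevel=2)
    return ProcessedEMG(env, muscle_names=manifest["muscles"],
                        provenance=manifest["provenance"])


def write_task(path, tau: TaskVariable) -> None:
    path = Path(path)
    if tau.kind == "discrete":
        df = pd.DataFrame({"trial": np.arange(len(tau.values)), "label": tau.values})
    else:
        n, t = tau.values.shape
        trial, tp = np.meshgrid(np.arange(n), np.arange(t), indexing="ij")
        df = pd.DataFrame({"trial": trial.ravel(), "timepoint": tp.ravel(),
                           "value": tau.values.ravel()})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    write_json(path.with_suffix(".manifest.json"),
               {"kind": tau.kind, "name": tau.name})


def read_task(path) -> TaskVariable:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"task file not found: {path}")
    manifest = read_json(path.with_suffix(".manifest.json"))
    df = pd.read_csv(path)
    if manifest["kind"] == "discrete":
        values = df.sort_values("trial")["label"].to_numpy()
    else:
        n = df["trial"].max() + 1
        t = df["timepoint"].max() + 1
        values = np.zeros((n, t))
        values[df["trial"], df["timepoint"]] = df["value"]
    return TaskVariable(manifest["kind"], values, name=manifest["name"])


def write_tensor(path, tensor: CouplingTensor) -> None:
    np.savez_compressed(
        Path(path), values=tensor.values,
        muscle_pairs=np.asarray(tensor.muscle_pairs),
        time_pairs=np.asarray(tensor.time_pairs),
        layer_labels=np.asarray([f"{t}::{p}" for t, p in tensor.layer_labels]),
        meta=np.asarray([tensor.interaction, str(tensor.n_muscles),
                         str(tensor.n_timepoints)]),
    )


def read_tensor(path) -> CouplingTensor:
    with np.load(Path(path), allow_pickle=False) as z:
        interaction, n_muscles, n_time = z["meta"]
        labels = [tuple(s.split("::")) for s in z["layer_labels"]]
        labels = [(t, int(p)) for t, p in labels]
        return CouplingTensor(z["values"], [tuple(p) for p in z["muscle_pairs"]],
                              [tuple(p) for p in z["time_pairs"]], labels,
                              str(interaction), int(n_muscles), int(n_time))


def write_decomposition(path, dec: SpaceTimeDecomposition) -> None:
    np.savez_compressed(Path(path), W=dec.W, V=dec.V, S=dec.S,
                        residual=np.asarray([dec.residual]),
                        objective=dec.objective_history)


def read_decomposition(path) -> SpaceTimeDecomposition:
    with np.load(Path(path)) as z:
        return SpaceTimeDecomposition(z["W"], z["V"], z["S"],
                                      float(z["residual"][0]), z["objective"])


def write_network_graphml(path, adj, node_names=None, partition=None,
                          centrality=None) -> None:
    """Weighted network with optional community / centrality attributes."""
    adj = np.asarray(adj, dtype=float)
    g = nx.Graph()
    n = adj.shape[0]
    names = list(node_names) if node_names else [str(i) for i in range(n)]
    for i in range(n):
        attrs = {}
        if partition is not None:
            attrs["community"] = int(partition.assignment[i])
        if centrality is not None:
            attrs["communicability"] = float(centrality[i])
        g.add_node(names[i], **attrs)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j] > 0:
                g.add_edge(names[i], names[j], weight=float(adj[i, j]))
    nx.write_graphml(g, Path(path))
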