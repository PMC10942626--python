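"""End-to-end orchestration of the task-space coupling pipeline.

Stage order: preprocess -> couple (three interaction classes) ->
percolation sparsify (dual domain) -> model-rank selection -> space-time
factorisation -> subnetwork analysis -> robustness.  Every artifact is
written with provenance (config digest, seed, package version).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from ._exceptions import ValidationError
from .config import PipelineConfig, stage_seed
from .coupling import build_tensors
from .modularity import ModularityParams, select_model_rank
from .netanalysis import communicability, factor_to_network, prune_below_average, submodules
from .percolation import sparsify_tensor
from .robustness import leave_n_out, random_ablation
from .trifactor import FitOptions, snm3f_fit
from . import io as mio

__all__ = ["run_pipeline"]

log = logging.getLogger("myotask")


def _fit_options(config: PipelineConfig, seed: int) -> FitOptions:
    return FitOptions(max_iter=config.max_iter, tol=config.tol,
                      n_restarts=config.n_restarts, seed=seed,
                      orthogonality_weight_v=config.orthogonality_weight_v,
                      orthogonality_weight_w=config.orthogonality_weight_w)


def run_pipeline(emg_list, tasks, out_dir, config: PipelineConfig | None = None,
                 run_robustness: bool = True) -> dict:
    """Run the full chain on preprocessed envelopes and task variables.

    Returns a dict of in-memory results; writes artifacts under ``out_dir``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    log.info("coupling: %d participants, %d tasks", len(emg_list), len(tasks))
    tensors = build_tensors(emg_list, tasks)
    for cls, tensor in tensors.items():
        mio.write_tensor(out / f"tensor_{cls}.npz", tensor)
    results["tensors"] = tensors

    sparse = {}
    ranks = {}
    decomps = {}
    analysis = {}
    robust = {}
    for cls, tensor in tensors.items():
        log.info("sparsify: %s", cls)
        sp = sparsify_tensor(tensor, n_random=config.n_random,
                             seed=stage_seed(config, "sparsify"),
                             statistic=config.null_statistic,
                             percentile=config.null_percentile)
        sparse[cls] = sp
        if not sp.mask.any():
            log.warning("%s: no couplings survived dual-domain sparsification", cls)
            continue

        rank = select_model_rank(
            sp, params=ModularityParams(config.gamma, config.omega),
            n_repeats=config.detection_repeats, seed=stage_seed(config, "rank"))
        ranks[cls] = rank

        opts = _fit_options(config, stage_seed(config, "decompose"))
        dec = snm3f_fit(sp.values, rank, opts)
        decomps[cls] = dec
        mio.write_decomposition(out / f"decomposition_{cls}.npz", dec)

        nets = []
        tensor_cls = tensors[cls]
        for fi in range(dec.spatial_rank):
            adj = factor_to_network(dec.V[fi], tensor_cls.muscle_pairs,
                                    tensor_cls.n_muscles)
            if adj.sum() == 0:
                continue
            prof = communicability(adj)
            pruned = prune_below_average(adj, prof)
            part = submodules(adj, n_repeats=config.detection_repeats,
                              seed=stage_seed(config, "analyze"))
            nets.append({"factor": fi, "partition": list(part.assignment),
                         "communicability": [float(c) for c in prof.node_total]})
            mio.write_network_graphml(out / f"network_{cls}_S{fi + 1}.graphml",
                                      pruned, partition=part,
                                      centrality=prof.node_total)
        analysis[cls] = nets

        if run_robustness and len(emg_list) >= 2:
            rep = leave_n_out(tensor_cls.copy_with(sp.values), rank,
                              axis="participant", opts=opts,
                              seed=stage_seed(config, "robustness"), reference=dec)
            robust[cls] = rep
            mio.write_json(out / f"robustness_{cls}.json",
                           {"summary": rep.summary(), "rows": rep.to_records()})

    mio.write_json(out / "ranks.json", {
        cls: {"spatial": r.spatial, "temporal": r.temporal, "provenance": r.provenance}
        for cls, r in ranks.items()})
    mio.write_json(out / "provenance.json", {
        "config_digest": config.digest(), "seed": config.seed,
        "version": __version__,
        "parameters": {
            "cutoff_hz": config.cutoff_hz, "n_samples": config.n_samples,
            "window": config.window, "gamma": config.gamma, "omega": config.omega,
            "n_random": config.n_random,
            "ablation_iterations": config.ablation_iterations,
        },
    })
    results.update(sparse=sparse, ranks=ranks, decompositions=decomps,
                   analysis=analysis, robustness=robust)
    return results
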