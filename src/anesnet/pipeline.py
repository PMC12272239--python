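"""End-to-end pipeline: simulate -> classify -> evoked -> network.

All randomness flows from the single configuration seed, so reruns with the
same configuration produce byte-identical summary files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CarpetMatrix
from .evoked import (EventDesign, extract_peristimulus, glm_block, response_metrics,
                     scale_to_percent)
from .io import write_events_tsv, write_matrix_tsv, write_parcellation_tsv
from .network import (ConsensusCommunities, average_strength, connectivity,
                      density_threshold, interhemispheric_correlation)
from .simdata import (SimulationConfig, StimulusDesign, make_parcellation,
                      simulate_state_run, simulate_visual_run)
from .states import BurstStateClassifier

log = logging.getLogger("anesnet")

ALL_STAGES = ("simulate", "classify", "evoked", "network")
ISO_STATES = ("burst_suppression", "single_burst", "no_bursts", "no_suppressions")


@dataclass
class PipelineConfig:
    """Serializable configuration for one pipeline invocation."""

    seed: int = 0
    out_dir: str = "anesnet_out"
    stages: tuple = ALL_STAGES
    simulate: dict = field(default_factory=dict)     # SimulationConfig overrides
    stimulus: dict = field(default_factory=dict)     # StimulusDesign overrides
    classifier: dict = field(default_factory=dict)   # BurstStateClassifier params
    network: dict = field(default_factory=lambda: {"gamma": 1.0, "density": 0.2,
                                                   "consensus_runs": 20})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)


def _sim_cfg(config: PipelineConfig, **overrides) -> SimulationConfig:
    kwargs = {**config.simulate, **overrides}
    return SimulationConfig(**kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and write artifacts plus a summary JSON.

    Returns the summary dictionary (also written to ``summary.json`` in the
    output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    summary: dict = {
        "version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "simulate": dict(config.simulate),
            "stimulus": dict(config.stimulus),
            "classifier": dict(config.classifier),
            "network": dict(config.network),
        },
    }
    state: dict = {}
    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            _STAGES[stage](config, state, summary, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _stage_simulate(config, state, summary, out: Path) -> None:
    carpets = []
    truths = {}
    for i, st in enumerate(ISO_STATES):
        cfg = _sim_cfg(config, state=st, seed=config.seed + i)
        carpet, truth = simulate_state_run(cfg)
        carpets.append(carpet)
        truths[st] = truth
        write_matrix_tsv(out / f"rest_{st}.tsv", carpet.data)
    awake_cfg = _sim_cfg(config, state="awake_like", seed=config.seed + 10)
    awake, awake_truth = simulate_state_run(awake_cfg)
    write_matrix_tsv(out / "rest_awake_like.tsv", awake.data)
    parc, modules = make_parcellation(awake_cfg.n_nodes,
                                      awake_cfg.module_count_per_hemisphere)
    write_parcellation_tsv(out / "parcellation.tsv", parc)
    design = StimulusDesign(**config.stimulus)
    vis_cfg = _sim_cfg(config, seed=config.seed + 20)
    visual, vis_truth, events = simulate_visual_run(vis_cfg, design)
    write_matrix_tsv(out / "visual_run.tsv", visual.data)
    write_events_tsv(out / "visual_events.tsv", events)
    truth_json = {
        "planted_modules": modules.tolist(),
        "planted_burst_times": {st: list(truths[st].burst_times) for st in ISO_STATES},
        "planted_response_amplitude": vis_truth.response_amplitude.tolist(),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
    state.update(carpets=carpets, truths=truths, awake=awake, awake_truth=awake_truth,
                 parcellation=parc, planted_modules=modules, visual=visual,
                 visual_truth=vis_truth, events=events, design=design,
                 vis_cfg=vis_cfg)
    summary["simulate"] = {
        "states": list(ISO_STATES) + ["awake_like"],
        "n_voxels": carpets[0].n_voxels,
        "run_length_volumes": carpets[0].n_time,
    }


def _stage_classify(config, state, summary, out: Path) -> None:
    carpets = state["carpets"]
    data = np.concatenate([c.data for c in carpets], axis=1)
    boundaries, cursor = [], 0
    for c in carpets:
        boundaries.append((cursor, cursor + c.n_time))
        cursor += c.n_time
    carpet = CarpetMatrix(data, tr_seconds=carpets[0].tr_seconds,
                          run_boundaries=boundaries,
                          voxel_labels=carpets[0].voxel_labels)
    clf = BurstStateClassifier(tr_seconds=carpet.tr_seconds, **config.classifier)
    clf.fit(carpet)
    segments = clf.segments_.copy()
    segments["condition"] = [carpets[r].condition for r in segments["run"]]
    segments.to_csv(out / "segments.tsv", sep="\t", index=False, float_format="%.9g")
    write_matrix_tsv(out / "pc1.tsv", np.vstack([clf.pca_.pc1, clf.pc1_normalized_]),
                     ids=["pc1", "pc1_normalized"])
    counts = segments.groupby(["condition", "state"]).size()
    summary["classify"] = {
        "n_segments": int(len(segments)),
        "explained_variance_ratio": float(clf.pca_.explained_variance_ratio),
        "state_counts": {f"{c}/{s}": int(v) for (c, s), v in counts.items()},
        "accuracy_vs_planted": float(
            np.mean(segments["condition"].to_numpy() == segments["state"].to_numpy())
        ),
    }
    state["segments"] = segments


def _stage_evoked(config, state, summary, out: Path) -> None:
    visual = state["visual"]
    design_obj = state["design"]
    events = state["events"]
    vis_cfg = state["vis_cfg"]
    pct = scale_to_percent(visual.data)
    design = EventDesign(events["onset"].to_numpy(), events["duration"].to_numpy(),
                         run_length_volumes=visual.n_time, tr=visual.tr_seconds)
    res = glm_block(pct, design)
    rows = []
    for i in range(pct.shape[0]):
        trace = extract_peristimulus(pct[i], design)
        peak, auc = response_metrics(trace)
        rows.append({"node": i, "beta": float(np.atleast_1d(res.beta)[i]),
                     "tstat": float(np.atleast_1d(res.tstat)[i]),
                     "peak_pct": peak, "auc": auc,
                     "n_epochs": trace.n_epochs_averaged})
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "evoked_metrics.tsv", sep="\t", index=False,
                   float_format="%.9g")
    planted = state["visual_truth"].response_amplitude
    summary["evoked"] = {
        "mean_beta": float(metrics["beta"].mean()),
        "mean_peak_pct": float(metrics["peak_pct"].mean()),
        "mean_auc": float(metrics["auc"].mean()),
        "mean_planted_amplitude": float(np.mean(planted)),
        "glm_dof": int(res.dof),
    }


def _stage_network(config, state, summary, out: Path) -> None:
    awake = state["awake"]
    parc = state["parcellation"]
    net_cfg = config.network
    a = connectivity(awake.data)
    write_matrix_tsv(out / "awake_adjacency.tsv", a)
    cons = ConsensusCommunities(gamma=net_cfg.get("gamma", 1.0),
                                n_runs=net_cfg.get("consensus_runs", 20),
                                seed=config.seed).fit(a)
    pd.DataFrame({"node": np.arange(a.shape[0]),
                  "module": cons.labels_}).to_csv(out / "awake_partition.tsv",
                                                  sep="\t", index=False)
    thr = density_threshold(a, net_cfg.get("density", 0.2))
    inter = interhemispheric_correlation(a, parc)
    from sklearn.metrics import adjusted_rand_score

    summary["network"] = {
        "n_modules": int(cons.n_modules_),
        "modularity_q": float(cons.q_),
        "ari_vs_planted": float(
            adjusted_rand_score(state["planted_modules"], cons.labels_)
        ),
        "interhemispheric_rho": float(inter["rho"]),
        "average_strength": float(average_strength(a)),
        "thresholded_edges": int(np.count_nonzero(np.triu(thr, k=1))),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "evoked": _stage_evoked,
    "network": _stage_network,
}
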