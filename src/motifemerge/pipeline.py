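"""End-to-end experiment: data -> training -> pruned graphs -> motif profiles.

Runs the full grid (2 learning environments x 3 initialization schemes for
one named architecture), snapshots the connection graph before and after
learning, mines motifs at the requested sizes against a degree-preserving
null ensemble, and writes machine-readable reports: per-cell edge lists,
GraphML, profile/delta CSVs and a JSON summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import datasets as ds
from . import graph_extraction as gx
from . import mlp
from . import motifs as mm

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "weight_statistics",
    "compare_convergence",
    "plot_profile_csv",
    "load_config_yaml",
]

logger = logging.getLogger("motifemerge")

DATASET_KINDS = ("tree", "clusters")
INIT_SCHEMES = ("normal", "orthogonal", "glorot")


@dataclass(frozen=True)
class ExperimentConfig:
    """One full experiment; the global seed determines every stochastic
    stage (data generation, initialization, batching, null replicas)."""

    tree: ds.TreeConfig = field(default_factory=ds.TreeConfig)
    clusters: ds.ClustersConfig = field(default_factory=ds.ClustersConfig)
    arch_name: str = "240120"
    train: mlp.TrainConfig = field(default_factory=mlp.TrainConfig)
    prune: gx.PruneConfig = field(default_factory=gx.PruneConfig)
    null_model: mm.NullModelConfig = field(default_factory=mm.NullModelConfig)
    motif_sizes: tuple[int, ...] = (4, 5)
    colored: bool = True
    out_dir: str = "motifemerge_out"
    seed: int = 240120


@dataclass
class ExperimentReport:
    cells: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.cells, indent=2, sort_keys=True, default=float)
        )


def _derived_seeds(global_seed: int, n: int) -> list[int]:
    """Deterministic stream of sub-seeds (< 2**31) from the global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]


def weight_statistics(before: np.ndarray, after: np.ndarray) -> dict[str, float]:
    """Mean and sd of absolute retained weights, before vs after learning."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("empty retention: no weights survive pruning")
    return {
        "mean_abs_before": float(np.abs(before).mean()),
        "sd_abs_before": float(np.abs(before).std()),
        "mean_abs_after": float(np.abs(after).mean()),
        "sd_abs_after": float(np.abs(after).std()),
    }


def _mine_graph(graph, sizes, null_config, colored):
    profiles = {}
    for k in sizes:
        census = mm.enumerate_connected_subgraphs(graph, k, colored)
        ensemble = mm.null_census_ensemble(graph, k, null_config, colored)
        profiles[k] = mm.z_scores(census, ensemble)
    return profiles


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the grid; a failure in one cell is recorded and the rest of
    the grid still runs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ExperimentReport()
    seeds = _derived_seeds(config.seed, 2 + 2 * len(INIT_SCHEMES) * 2)
    seed_iter = iter(seeds)

    data: dict[str, ds.Dataset] = {}
    for kind in DATASET_KINDS:
        t0 = time.perf_counter()
        base = config.tree if kind == "tree" else config.clusters
        cfg = type(base)(**{**asdict(base), "seed": next(seed_iter)})
        data[kind] = (ds.generate_tree_dataset(cfg) if kind == "tree"
                      else ds.generate_clusters_dataset(cfg))
        ds.write_dataset_csv(data[kind], out / f"dataset_{kind}.csv")
        logger.info("generated %s dataset in %.2fs", kind,
                    time.perf_counter() - t0)

    arch = mlp.MLPArchitecture.from_preset(config.arch_name)
    for kind in DATASET_KINDS:
        for scheme in INIT_SCHEMES:
            cell = f"{kind}/{scheme}"
            cell_dir = out / kind / scheme
            cell_dir.mkdir(parents=True, exist_ok=True)
            train_seed = next(seed_iter)
            null_seed = next(seed_iter)
            try:
                report.cells[cell] = _run_cell(
                    arch, data[kind], config, cell_dir, train_seed, null_seed
                )
            except Exception as err:  # keep the rest of the grid alive
                logger.exception("cell %s failed", cell)
                report.cells[cell] = {"status": "failed",
                                      "stage": getattr(err, "stage", "unknown"),
                                      "error": str(err)}
    report.to_json(out / "summary.json")
    return report


def _run_cell(arch, dataset, config: ExperimentConfig, cell_dir: Path,
              train_seed: int, null_seed: int) -> dict[str, Any]:
    train_cfg = mlp.TrainConfig(**{**asdict(config.train),
                                   "init_scheme": _scheme_of(cell_dir),
                                   "seed": train_seed})
    t0 = time.perf_counter()
    result = mlp.train(arch, dataset, train_cfg)
    logger.info("%s trained %d epochs in %.2fs", cell_dir, result.epochs_run,
                time.perf_counter() - t0)

    result.initial_params.save_json(cell_dir / "params_initial.json")
    result.final_params.save_json(cell_dir / "params_final.json")
    _write_trace(result, cell_dir / "trace.csv")

    graphs = {}
    retained = {}
    for stage, params in (("before", result.initial_params),
                          ("after", result.final_params)):
        graph = gx.model_to_graph(params, config.prune)
        graphs[stage] = graph
        retained[stage] = np.array(
            [d["weight"] for _, _, d in graph.edges(data=True)]
        )
        gx.write_edge_list(graph, cell_dir / f"edges_{stage}.txt",
                           colored=config.colored)
        gx.write_graphml(graph, cell_dir / f"graph_{stage}.graphml")

    stats = weight_statistics(retained["before"], retained["after"])

    null_cfg = mm.NullModelConfig(**{**asdict(config.null_model),
                                     "seed": null_seed})
    profiles = {}
    deltas = {}
    for stage in ("before", "after"):
        t0 = time.perf_counter()
        profiles[stage] = _mine_graph(graphs[stage], config.motif_sizes,
                                      null_cfg, config.colored)
        logger.info("%s mined %s graph in %.2fs", cell_dir, stage,
                    time.perf_counter() - t0)
        for k, profile in profiles[stage].items():
            mm.profile_to_csv(profile, cell_dir / f"profile_k{k}_{stage}.csv")
    for k in config.motif_sizes:
        deltas[k] = mm.profile_delta(profiles["before"][k],
                                     profiles["after"][k])
        _write_deltas(profiles["before"][k], profiles["after"][k],
                      deltas[k], cell_dir / f"delta_k{k}.csv")

    return {
        "status": "ok",
        "epochs_to_perfect": result.epochs_to_perfect,
        "final_accuracy": result.accuracy_trace[-1],
        "max_accuracy": max(result.accuracy_trace),
        "weight_statistics": stats,
        "edges_before": int(graphs["before"].number_of_edges()),
        "edges_after": int(graphs["after"].number_of_edges()),
        "n_motif_classes": {
            str(k): len(profiles["after"][k].entries)
            for k in config.motif_sizes
        },
    }


def _scheme_of(cell_dir: Path) -> str:
    return cell_dir.name


def _write_trace(result: mlp.TrainResult, path: Path) -> None:
    import pandas as pd

    pd.DataFrame({
        "epoch": np.arange(1, result.epochs_run + 1),
        "accuracy": result.accuracy_trace,
        "loss": result.loss_trace,
    }).to_csv(path, index=False)


def _write_deltas(before: mm.SignificanceProfile, after: mm.SignificanceProfile,
                  deltas: dict[int, float | None], path: Path) -> None:
    import pandas as pd

    rows = []
    for code in sorted(deltas):
        zb = before.entries[code].z if code in before.entries else 0.0
        za = after.entries[code].z if code in after.entries else 0.0
        rows.append({
            "k": before.k,
            "canonical_code": code,
            "Z_before": np.nan if zb is None else zb,
            "Z_after": np.nan if za is None else za,
            "delta": np.nan if deltas[code] is None else deltas[code],
        })
    pd.DataFrame(rows, columns=["k", "canonical_code", "Z_before", "Z_after",
                                "delta"]).to_csv(path, index=False)


def compare_convergence(
    epochs_by_cell: dict[tuple[str, str], list[int | None]],
    max_epochs: int,
) -> dict[str, Any]:
    """Median epochs-to-perfect per (dataset, scheme) across seeds.

    Runs that never reached accuracy 1.0 are censored at ``max_epochs``.
    With identical medians no ordering is claimed; with fewer than 3 seeds
    a low-confidence flag is raised.
    """
    summary: dict[str, Any] = {"datasets": {}}
    n_seeds = min((len(v) for v in epochs_by_cell.values()), default=0)
    summary["n_seeds"] = n_seeds
    summary["low_confidence"] = n_seeds < 3
    kinds = sorted({kind for kind, _ in epochs_by_cell})
    for kind in kinds:
        medians = {}
        censored = {}
        for (k, scheme), values in epochs_by_cell.items():
            if k != kind:
                continue
            filled = [max_epochs if v is None else v for v in values]
            medians[scheme] = float(np.median(filled))
            censored[scheme] = sum(v is None for v in values)
        if len(set(medians.values())) == 1:
            ordering = None  # tie: no ordering claimed
            normal_slowest = None
        else:
            ordering = sorted(medians, key=lambda s: medians[s])
            normal_slowest = ("normal" in medians
                              and medians["normal"] == max(medians.values()))
        summary["datasets"][kind] = {
            "median_epochs": medians,
            "censored_runs": censored,
            "ordering_fastest_to_slowest": ordering,
            "normal_slowest": normal_slowest,
        }
    return summary


def plot_profile_csv(csv_path: str | Path, out_path: str | Path) -> None:
    """Bar chart of the Z-scores in a profile CSV (motif classes on x)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    frame = pd.read_csv(csv_path).dropna(subset=["Z"])
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(frame)), 3))
    ax.bar(range(len(frame)), frame["Z"])
    ax.set_xticks(range(len(frame)))
    ax.set_xticklabels(frame["canonical_code"], rotation=90, fontsize=6)
    ax.set_ylabel("Z")
    ax.set_xlabel("motif class (canonical code)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config_yaml(path: str | Path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file.

    Recognized blocks: ``data`` (depth, epsilon, distinction_level, n_nodes,
    n_groups, spread, n_samples, seed), ``train``, ``prune``, ``null_model``,
    ``experiment`` (arch, motif_sizes, colored, out_dir, seed).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    data = raw.get("data", {})
    tree_kwargs = {}
    for src, dst in (("depth", "depth"), ("epsilon", "flip_threshold"),
                     ("distinction_level", "distinction_level"),
                     ("n_samples", "n_samples"), ("seed", "seed")):
        if src in data:
            tree_kwargs[dst] = data[src]
    clusters_kwargs = {}
    for src in ("n_nodes", "n_groups", "spread", "n_samples", "seed"):
        if src in data:
            clusters_kwargs[src] = data[src]
    exp = raw.get("experiment", {})
    return ExperimentConfig(
        tree=ds.TreeConfig(**tree_kwargs),
        clusters=ds.ClustersConfig(**clusters_kwargs),
        arch_name=exp.get("arch", "240120"),
        train=mlp.TrainConfig(**raw.get("train", {})),
        prune=gx.PruneConfig(**raw.get("prune", {})),
        null_model=mm.NullModelConfig(**raw.get("null_model", {})),
        motif_sizes=tuple(exp.get("motif_sizes", (4, 5))),
        colored=exp.get("colored", True),
        out_dir=exp.get("out_dir", "motifemerge_out"),
        seed=exp.get("seed", 240120),
    )
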