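"""End-to-end orchestration: simulate/load -> clean -> weighted
connectivity -> threshold -> global metrics -> modules & hubs ->
condition contrast, with a density sweep and reproducible outputs.

The report density defaults to 0.30 (all nodes in the giant component,
metrics stabilized) but the full grid 0.10-0.50 is computed and written.
Every run is driven by one master seed; a manifest with SHA-256 hashes
of all outputs supports byte-level reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import graphs as gr
from . import modules as mod
from . import stats as st
from .preprocess import clean_timeseries
from .roi import load_ground_truth_partition, load_roi_table
from .synth import PRESETS, default_ground_truth, generate_cohort, read_session

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "density_sweep",
           "subject_condition_matrices", "group_graph"]

log = logging.getLogger("painnet")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults = the study's constants)."""

    preset: str = "group1"
    n_subjects: int | None = None
    n_sessions: int | None = None
    densities: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)
    report_density: float = 0.30
    n_restarts: int = 100
    n_perm: int = 5000
    null_realizations: int = 100
    subject_null_realizations: int = 20
    subject_n_restarts: int = 20
    wmd_min: float = 1.0
    pc_min: float = 0.45
    pc_mode: str = "fixed"
    alpha: float = 0.01
    cutoff_hz: float = 0.01
    combine: str = "mean_z"
    run_contrast: bool = True
    write_subject_matrices: bool = False
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not all(0 < d <= 1 for d in self.densities):
            raise ValueError("densities must lie in (0, 1]")
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; options: {list(PRESETS)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "densities" in payload:
            payload["densities"] = tuple(payload["densities"])
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    roi_labels: list[str]
    partition: mod.ModularPartition
    metrics: gr.GlobalMetrics
    hub_table: pd.DataFrame
    sweep: pd.DataFrame
    link_stats: dict
    contrast: st.ConditionContrast | None
    group_matrices: dict
    group_graphs: dict
    summary: dict
    out_dir: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapper
    return deco


def subject_condition_matrices(cohort, condition: str, cutoff_hz=0.01,
                               node_subset: list[str] | None = None,
                               combine: str = "mean_z") -> dict:
    """Per-subject Fisher-z matrices for one condition (cleaning included).

    ``node_subset`` restricts the analysis to those node labels (e.g. the
    34-node pain network out of an audio-augmented cohort).
    """
    out = {}
    for sub, sessions in cohort.items():
        cleaned, weights = [], []
        for ts in sessions:
            if condition not in ts.designs:
                raise PipelineError(
                    f"session {ts.subject_id}/{ts.session_id} has no "
                    f"{condition!r} events"
                )
            c = clean_timeseries(ts, cutoff_hz=cutoff_hz)
            if node_subset is not None:
                idx = [c.node_labels.index(lab) for lab in node_subset]
                c.X = c.X[idx]
                c.node_labels = list(node_subset)
            cleaned.append(c)
            weights.append(conn.stimulus_weights(ts.designs[condition]))
        out[sub] = conn.build_condition_matrix(cleaned, weights, condition,
                                               combine=combine)
    return out


def group_graph(subject_mats: dict, density: float):
    """Threshold subjects, average, re-threshold: the group graph.

    Returns (group ConnectivityMatrix of thresholded-subject means,
    group ThresholdedGraph at the same density)."""
    thr = []
    for m in subject_mats.values():
        g = gr.proportional_threshold(m, density)
        thr.append(conn.ConnectivityMatrix(
            Z=g.A, node_labels=m.node_labels, condition=m.condition,
            level="subject", density=density,
        ))
    gavg = conn.group_average(thr)
    graph = gr.proportional_threshold(
        conn.ConnectivityMatrix(Z=gavg.Z, node_labels=gavg.node_labels,
                                condition=gavg.condition, level="group"),
        density,
    )
    return gavg, graph


def density_sweep(subject_mats_by_condition: dict, config: RunConfig,
                  seed: int | None = None) -> pd.DataFrame:
    """Global metrics (with shuffled-weight nulls) across the density grid.

    One row per density x condition; includes edge counts and the
    C_random / L_random ensemble means behind each sigma.
    """
    if len(config.densities) < 2:
        raise PipelineError("density sweep needs at least 2 densities")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    rows = []
    for cond, mats in subject_mats_by_condition.items():
        for d, child in zip(config.densities, ss.spawn(len(config.densities))):
            s1, s2 = (int(x) for x in child.generate_state(2) % (2**31))
            gavg, graph = group_graph(mats, d)
            null = gr.random_equivalents(
                gavg, n_realizations=config.null_realizations, seed=s1, density=d,
            )
            part = mod.optimize_partition(graph, n_restarts=config.n_restarts, seed=s2)
            m = gr.global_metrics(graph, partition=part, null=null)
            row = {"condition": cond, "n_modules": part.n_modules,
                   "edge_count": graph.edge_count, **m.to_dict()}
            rows.append(row)
    return pd.DataFrame(rows)


def _per_subject_global_metrics(subject_mats: dict, config: RunConfig,
                                seed: int) -> pd.DataFrame:
    """Per-subject C/L/Q/A/sigma/average strength at the report density."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for (sub, m), child in zip(sorted(subject_mats.items()), ss.spawn(len(subject_mats))):
        s1, s2 = (int(x) for x in child.generate_state(2) % (2**31))
        g = gr.proportional_threshold(m, config.report_density)
        null = gr.random_equivalents(
            g, n_realizations=config.subject_null_realizations, seed=s1)
        part = mod.optimize_partition(g, n_restarts=config.subject_n_restarts, seed=s2)
        met = gr.global_metrics(g, partition=part, null=null)
        rows.append({
            "subject": sub, "C": met.C, "L": met.L, "Q": met.Q, "A": met.A,
            "sigma": met.sigma,
            "average_strength": float(g.A.sum(axis=1).mean()),
        })
    return pd.DataFrame(rows).set_index("subject")


def _link_proportions(subject_mats: dict, partition: mod.ModularPartition,
                      config: RunConfig) -> pd.DataFrame:
    """Per-subject intra/inter link fractions at the report density, under
    the group partition."""
    rows = []
    for sub, m in sorted(subject_mats.items()):
        g = gr.proportional_threshold(m, config.report_density)
        ls = mod.modular_link_stats(g, partition)
        rows.append({
            "subject": sub,
            "intra_fraction": ls["intra_fraction"],
            "inter_fraction": 1.0 - ls["intra_fraction"],
        })
    return pd.DataFrame(rows).set_index("subject")


@_stage("simulate")
def _simulate(config: RunConfig, seed: int):
    preset = PRESETS[config.preset]
    include_audio = preset.audio_n_stimuli > 0
    table = load_roi_table(include_audio_nodes=include_audio)
    gt_part = load_ground_truth_partition(table)
    gt = default_ground_truth(gt_part)
    cohort, gt = generate_cohort(
        table, gt, n_subjects=config.n_subjects, n_sessions=config.n_sessions,
        preset=preset, seed=seed,
    )
    return table, cohort, gt


def load_cohort(data_dir, config: RunConfig) -> dict:
    """Read sub-*_ses-* TSV trios from a directory into a cohort dict."""
    data_dir = Path(data_dir)
    preset = PRESETS[config.preset]
    cohort: dict[str, list] = {}
    ts_files = sorted(data_dir.glob("sub-*_ses-*_timeseries.tsv"))
    if not ts_files:
        raise PipelineError(f"no sub-*_ses-*_timeseries.tsv files in {data_dir}")
    for ts_path in ts_files:
        stem = ts_path.name.replace("_timeseries.tsv", "")
        sub, ses = stem.split("_", 1)
        ev = ts_path.with_name(f"{stem}_events.tsv")
        cf = ts_path.with_name(f"{stem}_confounds.tsv")
        if not ev.exists():
            raise PipelineError(f"missing events file for session {stem}: {ev}")
        if not cf.exists():
            raise PipelineError(f"missing confounds file for session {stem}: {cf}")
        cohort.setdefault(sub, []).append(read_session(
            ts_path, TR=preset.TR, events_path=ev, confounds_path=cf,
            subject_id=sub, session_id=ses,
        ))
    return cohort


def run_pipeline(config: RunConfig, data_dir=None) -> PipelineResult:
    """Execute the full analysis; synthetic cohort unless ``data_dir``.

    Writes tables, graphs, partitions and a machine-readable
    ``summary.json`` + hash manifest under ``config.out_dir`` when set.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(x) for x in ss.generate_state(8) % (2**31)]
    preset = PRESETS[config.preset]
    has_audio = preset.audio_n_stimuli > 0

    if data_dir is None:
        table, cohort, gt = _simulate(config, seeds[0])
    else:
        include_audio = has_audio
        table = load_roi_table(include_audio_nodes=include_audio)
        cohort = load_cohort(data_dir, config)
        gt = None

    pain_nodes = [r.label for r in table if not r.in_audio_only]

    # --- connectivity ------------------------------------------------------
    try:
        pain_mats = subject_condition_matrices(
            cohort, "pain", cutoff_hz=config.cutoff_hz,
            node_subset=pain_nodes, combine=config.combine,
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage 'connectivity' failed: {e}") from e

    # --- group graph at the report density --------------------------------
    gavg, graph = group_graph(pain_mats, config.report_density)
    null = gr.random_equivalents(
        gavg, n_realizations=config.null_realizations, seed=seeds[1],
        density=config.report_density,
    )
    partition = mod.optimize_partition(graph, n_restarts=config.n_restarts,
                                       seed=seeds[2])
    metrics = gr.global_metrics(graph, partition=partition, null=null)
    profiles = mod.node_profiles(graph, partition)
    hubs = mod.classify_hubs(
        profiles, null, wmd_min=config.wmd_min, pc_min=config.pc_min,
        alpha=config.alpha, pc_mode=config.pc_mode,
    )
    link_stats = mod.modular_link_stats(graph, partition)

    # --- density sweep -----------------------------------------------------
    sweep = density_sweep({"pain": pain_mats}, config, seed=seeds[3])

    # --- pain vs audio contrast (36-node network) --------------------------
    contrast = None
    group_matrices = {"pain": gavg}
    group_graphs = {"pain": graph}
    if has_audio and config.run_contrast:
        pain36 = subject_condition_matrices(
            cohort, "pain", cutoff_hz=config.cutoff_hz, combine=config.combine)
        audio36 = subject_condition_matrices(
            cohort, "audio", cutoff_hz=config.cutoff_hz, combine=config.combine)
        gm_pain = _per_subject_global_metrics(pain36, config, seeds[4])
        gm_audio = _per_subject_global_metrics(audio36, config, seeds[4] + 1)
        gavg_a, graph_a = group_graph(audio36, config.report_density)
        part_a = mod.optimize_partition(graph_a, n_restarts=config.n_restarts,
                                        seed=seeds[5])
        lp_pain = _link_proportions(pain36, part_a, config)
        lp_audio = _link_proportions(audio36, part_a, config)
        contrast = st.compare_conditions(
            pain36, audio36, n_perm=config.n_perm, seed=seeds[6],
            global_pain=gm_pain, global_audio=gm_audio,
            link_pain=lp_pain[["intra_fraction", "inter_fraction"]],
            link_audio=lp_audio[["intra_fraction", "inter_fraction"]],
        )
        group_matrices["audio"] = gavg_a
        group_graphs["audio"] = graph_a

    sizes = sorted(partition.module_sizes.tolist(), reverse=True)
    summary = {
        "config": config.to_dict(),
        "n_nodes": len(pain_nodes),
        "n_subjects": len(cohort),
        "report_density": config.report_density,
        "Q": partition.Q,
        "n_modules": partition.n_modules,
        "module_sizes": sizes,
        "modules": {str(c): partition.members(c) for c in range(partition.n_modules)},
        "C": metrics.C, "L": metrics.L, "A": metrics.A, "sigma": metrics.sigma,
        "coverage": metrics.coverage,
        "static_hubs": hubs.loc[hubs.hub_static, "node"].tolist(),
        "dynamical_hubs": hubs.loc[hubs.hub_dynamical, "node"].tolist(),
        "connector_hubs": hubs.loc[hubs.hub_connector, "node"].tolist(),
        "intra_fraction": link_stats["intra_fraction"],
        "average_strength": link_stats["average_strength"],
        "seed": config.seed,
    }
    if gt is not None:
        truth = {lab: gt.partition[lab] for lab in pain_nodes}
        rec = mod.compare_partitions(
            partition.as_mapping(),
            {lab: truth[lab] for lab in partition.node_labels},
        )
        summary["ground_truth_recovery"] = rec
    if contrast is not None:
        summary["contrast"] = {
            "n_edges_significant": int(contrast.edges["reject"].sum()),
            "global_metrics": contrast.global_metrics.to_dict(orient="records"),
            "link_stats": contrast.link_stats.to_dict(orient="records"),
        }

    result = PipelineResult(
        config=config, roi_labels=list(table.labels), partition=partition,
        metrics=metrics, hub_table=hubs, sweep=sweep, link_stats=link_stats,
        contrast=contrast, group_matrices=group_matrices,
        group_graphs=group_graphs, summary=summary,
    )
    if config.out_dir is not None:
        result.out_dir = write_outputs(result, Path(config.out_dir))
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []

    def save(name, writer):
        path = out_dir / name
        writer(path)
        files.append(path)

    for cond, m in result.group_matrices.items():
        save(f"group_matrix_{cond}.csv", m.write)
    for cond, g in result.group_graphs.items():
        save(f"group_graph_{cond}.graphml", g.write_graphml)
        save(f"group_edges_{cond}.tsv",
             lambda p, g=g: g.to_edge_list().to_csv(p, sep="\t", index=False))
    save("partition_pain.json", lambda p: Path(p).write_text(
        json.dumps(result.partition.as_mapping(), indent=1, sort_keys=True)))
    save("hub_table.csv", lambda p: result.hub_table.to_csv(p, index=False))
    save("metrics_sweep.csv", lambda p: result.sweep.to_csv(p, index=False))
    if result.contrast is not None:
        save("contrast_edges.csv",
             lambda p: result.contrast.edges.to_csv(p, index=False))
        save("contrast_global_metrics.csv",
             lambda p: result.contrast.global_metrics.to_csv(p, index=False))
        save("contrast_link_stats.csv",
             lambda p: result.contrast.link_stats.to_csv(p, index=False))
    save("summary.json", lambda p: Path(p).write_text(
        json.dumps(result.summary, indent=1, sort_keys=True, default=float)))

    manifest = {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def check_manifest(out_dir) -> dict:
    """Re-hash declared outputs; returns {file: ok} and flags mismatches."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    status = {}
    for name, digest in manifest.items():
        f = out_dir / name
        status[name] = f.exists() and hashlib.sha256(f.read_bytes()).hexdigest() == digest
    return status
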