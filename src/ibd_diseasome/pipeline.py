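"""End-to-end pipeline orchestration.

``run_pipeline`` executes simulate -> cohort -> frequencies -> graph ->
communities -> robustness -> export from a single validated configuration,
writing every artifact plus a manifest (config echo, seed, version,
per-stage row/node/edge counts). Outputs are written to a ``.partial``
file first and renamed on completion, so an aborted stage leaves its
partial output identifiable. Fixed config => identical artifacts
(manifests differ only in their timestamp).
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, Field

from . import __version__
from .cohort import CaseDefinition, build_cohort, write_cohort
from .export import export_vis_json
from .freq import frequency_table, write_frequency_table
from .louvain import color_communities, louvain, write_partition_csv
from .network import build_graph, filter_graph, write_edge_list, write_graphml
from .robustness import (
    random_null,
    shuffle_profile,
    split_profile,
    write_results_csv,
)
from .synthetic_ehr import SimulationConfig, generate_cohort, write_ground_truth
from .records import write_records

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class SimulationSection(BaseModel):
    n_patients: int = 2000
    disease_mix: dict[str, float] = Field(
        default_factory=lambda: {"CD": 0.47, "UC": 0.35, "IBDU": 0.08, "non-case": 0.10}
    )
    n_communities: int = 4
    codes_per_community: int = 25
    p_within: float = 0.3
    p_between: float = 0.01
    case_noise: float = 0.0
    temporal_bias: float = 0.8


class GraphSection(BaseModel):
    cohort_tag: str = "IBD"
    min_pair_count: int = 1
    max_code_length: int | None = None
    top_n_pairs: int | None = 1000
    domains: list[str] | None = None
    mode: str = "cluster"  # cluster | icd-hierarchy


class RobustnessSection(BaseModel):
    n_shuffle_runs: int = 10
    n_split_trials: int = 5
    n_null_trials: int = 1000


class PipelineConfig(BaseModel):
    seed: int = 0
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    graph: GraphSection = Field(default_factory=GraphSection)
    robustness: RobustnessSection = Field(default_factory=RobustnessSection)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yml", ".yaml")
            else json.loads(text)
        )
        return cls.model_validate(data or {})


def _write(outdir: Path, name: str, writer) -> Path:
    """Write via a .partial temp name, renaming on success."""
    final = outdir / name
    partial = outdir / f"{name}.partial"
    writer(partial)
    partial.replace(final)
    return final


def run_pipeline(
    config: PipelineConfig | str | Path, outdir: str | Path
) -> dict[str, Any]:
    """Run every stage; returns the manifest (also written as JSON)."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.load(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.model_dump(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def stage(name, fn):
        try:
            result, info = fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise StageError(name, exc) from exc
        manifest["stages"][name] = info
        return result

    def _simulate():
        sim = SimulationConfig(seed=config.seed, **config.simulation.model_dump())
        records, truth = generate_cohort(sim)
        _write(outdir, "records.csv", lambda p: write_records(records, p))
        _write(outdir, "ground_truth.json", lambda p: write_ground_truth(truth, p))
        return (records, truth), {
            "n_records": len(records), "n_patients": sim.n_patients,
        }

    records, truth = stage("simulate", _simulate)

    def _cohort():
        cohort = build_cohort(
            records,
            CaseDefinition(),
            sex=truth.patient_sex,
            birth_date=truth.patient_birth_date,
        )
        _write(outdir, "cohort.csv", lambda p: write_cohort(cohort, p))
        counts: dict[str, int] = {}
        for c in cohort:
            counts[c.label] = counts.get(c.label, 0) + 1
        return cohort, {"labels": counts}

    cohort = stage("cohort", _cohort)

    def _freq():
        rows = frequency_table(records, cohort)
        _write(outdir, "frequencies.csv", lambda p: write_frequency_table(rows, p))
        return rows, {"n_rows": len(rows)}

    stage("frequencies", _freq)

    def _graph():
        g = build_graph(
            records,
            cohort,
            cohort_tag=config.graph.cohort_tag,
            min_pair_count=config.graph.min_pair_count,
        )
        g = filter_graph(
            g,
            min_pair_count=config.graph.min_pair_count,
            max_code_length=config.graph.max_code_length,
            top_n_pairs=config.graph.top_n_pairs,
            domain_subset=config.graph.domains,
        )
        return g, {"n_nodes": len(g.nodes), "n_edges": len(g.edges)}

    graph = stage("graph", _graph)

    def _communities():
        part = louvain(graph, edge_order=None)
        _write(outdir, "partition.csv", lambda p: write_partition_csv(part, p))
        return part, {
            "n_communities": part.n_communities,
            "modularity": part.modularity_Q,
        }

    partition = stage("communities", _communities)

    def _graph_export():
        _write(
            outdir,
            "graph.graphml",
            lambda p: write_graphml(graph, p, partition.assignment),
        )
        _write(outdir, "edges.csv", lambda p: write_edge_list(graph, p))
        return None, {"files": ["graph.graphml", "edges.csv"]}

    stage("graph-export", _graph_export)

    def _robustness():
        rb = config.robustness
        shuffle = shuffle_profile(graph, rb.n_shuffle_runs, config.seed)
        split = split_profile(
            records, cohort, rb.n_split_trials, config.seed,
            cohort_tag=config.graph.cohort_tag,
        )
        null = random_null(
            len(graph.nodes), partition.n_communities, rb.n_null_trials, config.seed
        )
        results = list(shuffle.values()) + list(split.values()) + [null]
        _write(outdir, "robustness.csv", lambda p: write_results_csv(results, p))
        return None, {
            "shuffle_mean": shuffle["all"].mean_overlap,
            "split_mean": split["all"].mean_overlap,
            "null_mean": null.mean_overlap,
        }

    stage("robustness", _robustness)

    def _export():
        payload = export_vis_json(
            graph,
            partition=partition,
            color_map=color_communities(partition),
            mode=config.graph.mode,
        )
        _write(
            outdir,
            "network.json",
            lambda p: Path(p).write_text(
                payload.model_dump_json(by_alias=True, indent=2)
            ),
        )
        return None, {"n_nodes": len(payload.nodes), "n_edges": len(payload.edges)}

    stage("export", _export)

    manifest["timestamp"] = dt.datetime.now(dt.timezone.utc).isoformat()
    _write(
        outdir,
        "manifest.json",
        lambda p: Path(p).write_text(json.dumps(manifest, indent=2)),
    )
    return manifest
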