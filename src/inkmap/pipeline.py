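"""End-to-end orchestration: load -> validate -> describe -> scale ->
[projection, SOM] -> indicators -> AutoCM -> MST/MRG -> export.

A single global seed fans out to per-stage seeds by fixed offsets, so a
stage rerun in isolation with its derived seed reproduces its part of a
full run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .autocm import AutoCMConfig, normalized_associations, train_autocm
from .cohort import (
    CohortTable,
    append_group_indicators,
    descriptive_stats,
    load_cohort,
    load_fixture,
    minmax_scale,
    validate_protocol,
)
from .graphs import association_to_distance, export_graph, minimum_spanning_tree, mrg_augment
from .projection import linear_separation_count, project_mds
from .som import SOMConfig, assign_classes, class_sharing_count, train_som

logger = logging.getLogger(__name__)

# per-stage seed offsets from the global seed
SEED_OFFSETS = {"som": 101, "autocm": 202, "mds": 303, "synthetic": 404}


class StageToggles(BaseModel):
    describe: bool = True
    validate_rules: bool = True
    mds: bool = True
    som: bool = True
    autocm: bool = True
    graph: bool = True


class MDSSettings(BaseModel):
    metric: Literal["euclidean", "manhattan"] = "euclidean"
    mode: Literal["classical", "smacof"] = "classical"


class SOMSettings(BaseModel):
    rows: int = 5
    cols: int = 5
    epochs: int = 1000
    lr_initial: float = 0.5
    lr_final: float = 0.02
    radius_initial: float = 1.5
    radius_final: float = 0.02
    decay: Literal["exponential", "linear"] = "exponential"
    init: Literal["random", "pca"] = "random"


class AutoCMSettings(BaseModel):
    contraction: float = 1.0
    learning_rate: float = 0.01
    init_weight: float = 0.01
    tolerance: float = 1e-6
    max_epochs: int = 10_000


class RunConfig(BaseModel):
    """Validated pipeline configuration (JSON-schema published via
    ``RunConfig.model_json_schema()``)."""

    input: str = "fixture"  # "fixture" or a CSV path
    stages: StageToggles = Field(default_factory=StageToggles)
    mds: MDSSettings = Field(default_factory=MDSSettings)
    som: SOMSettings = Field(default_factory=SOMSettings)
    autocm: AutoCMSettings = Field(default_factory=AutoCMSettings)
    graph_format: Literal["graphml", "dot", "csv"] = "graphml"
    top_k_edges: int = 50
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            payload = json.load(f)
        try:
            return cls.model_validate(payload)
        except ValidationError as exc:
            raise ValueError(f"invalid run configuration: {exc}") from exc


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run report.

    The report is a plain JSON-serializable dict; every number in it is
    regenerable from the config and seed.  A stage failure aborts the
    run with an error naming the stage.
    """
    toggles = config.stages
    if not any(toggles.model_dump().values()):
        raise ValueError("nothing to run: all stages disabled")
    logging.basicConfig(level=config.log_level)
    report: dict = {
        "version": __version__,
        "config": config.model_dump(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _artifact(name: str, path: Path) -> None:
        report["artifacts"][name] = str(path)

    def _stage(name: str):
        logger.info("running stage %s", name)

    try:
        table = load_fixture() if config.input == "fixture" else load_cohort(config.input)
    except Exception as exc:
        raise PipelineError("load", exc)
    report["n_subjects"] = table.n_subjects
    report["n_variables"] = table.n_variables

    if toggles.validate_rules:
        _stage("validate")
        try:
            vrep = validate_protocol(table)
        except Exception as exc:
            raise PipelineError("validate", exc)
        report["validation"] = vrep.to_dict()
        if out_dir:
            p = out_dir / "validation.json"
            p.write_text(json.dumps(vrep.to_dict(), indent=1))
            _artifact("validation", p)

    if toggles.describe:
        _stage("describe")
        try:
            stats = descriptive_stats(table)
        except Exception as exc:
            raise PipelineError("describe", exc)
        report["descriptive_stats"] = stats.to_dict(decimals=2)
        if out_dir:
            p = out_dir / "descriptive_stats.json"
            p.write_text(json.dumps(stats.to_dict(decimals=2), indent=1))
            _artifact("descriptive_stats", p)

    scaled = minmax_scale(table)

    if toggles.mds:
        _stage("mds")
        try:
            emb = project_mds(scaled, metric=config.mds.metric, mode=config.mds.mode,
                              seed=config.seed + SEED_OFFSETS["mds"])
            sep = linear_separation_count(emb)
        except Exception as exc:
            raise PipelineError("mds", exc)
        report["separation"] = {
            "misplaced_count": sep.misplaced_count,
            "misplaced_ids": sep.misplaced_ids,
            "stress": round(emb.stress, 6),
        }
        if out_dir:
            p = out_dir / "embedding.csv"
            with open(p, "w") as f:
                f.write("subject_id,group,x,y\n")
                for sid, g, (x, y) in zip(emb.subject_ids, emb.groups, emb.coords):
                    f.write(f"{sid},{g},{x!r},{y!r}\n")
            _artifact("embedding", p)

    if toggles.som:
        _stage("som")
        try:
            som_cfg = SOMConfig(**config.som.model_dump(),
                                seed=config.seed + SEED_OFFSETS["som"])
            model = train_som(scaled, som_cfg)
            assign = assign_classes(model, scaled)
        except Exception as exc:
            raise PipelineError("som", exc)
        report["som"] = {
            "classes": assign.classes,
            "shared_class_count": class_sharing_count(assign),
            "final_quantization_error": round(model.quantization_errors[-1], 6),
        }
        if out_dir:
            p = out_dir / "som_assignments.csv"
            with open(p, "w") as f:
                f.write("subject_id,group,class\n")
                for sid, g in zip(table.subject_ids, table.groups):
                    f.write(f"{sid},{g},{assign.classes[sid]}\n")
            _artifact("som_assignments", p)

    if toggles.autocm:
        _stage("autocm")
        try:
            with_ind = append_group_indicators(table)
            scaled47 = minmax_scale(with_ind)
            cm_cfg = AutoCMConfig(**config.autocm.model_dump(),
                                  seed=config.seed + SEED_OFFSETS["autocm"])
            state = train_autocm(scaled47, cm_cfg)
            assoc = normalized_associations(state)
        except Exception as exc:
            raise PipelineError("autocm", exc)
        report["autocm"] = {
            "n_units": len(assoc.variable_names),
            "epochs": state.epochs,
            "converged": state.converged,
            "saturation_gap": float(state.saturation_gap),
            "top_edges": [
                [u, v, round(s, 2)] for u, v, s in assoc.top_edges(config.top_k_edges)
            ],
        }
        if out_dir:
            p = out_dir / "associations.csv"
            assoc.to_csv(p)
            _artifact("associations", p)

        if toggles.graph:
            _stage("graph")
            try:
                mst = minimum_spanning_tree(
                    association_to_distance(assoc), assoc.variable_names
                )
                mrg = mrg_augment(mst, assoc)
            except Exception as exc:
                raise PipelineError("graph", exc)
            report["graph"] = {
                "kind": mrg.kind,
                "n_nodes": len(mrg.nodes),
                "n_edges": len(mrg.edges),
                "indicator_edges": {
                    ind: sorted(
                        other for u, v, _ in mrg.edges
                        for other in ((v,) if u == ind else (u,) if v == ind else ())
                    )
                    for ind in ("INPH", "DEMENZA")
                },
            }
            if out_dir:
                p = out_dir / f"graph.{config.graph_format}"
                export_graph(mrg, p, config.graph_format)
                _artifact("graph", p)
    return report


def write_report(report: dict, out_dir, formats: tuple[str, ...] = ("json",)) -> list[Path]:
    """Write the report; JSON always, optional human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats or True:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report, indent=1, default=_jsonable))
        written.append(p)
    if "text" in formats:
        p = out_dir / "report.txt"
        p.write_text(_summarize(report))
        written.append(p)
    return written


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _summarize(report: dict) -> str:
    lines = [f"inkmap {report.get('version', '?')} run report"]
    if "descriptive_stats" in report:
        nr = report["descriptive_stats"].get("Numero Risposte")
        if nr:
            lines.append(
                f"mean responses {nr['mean']:.2f} (min {nr['min']:.0f}, max {nr['max']:.0f})"
            )
    if "separation" in report:
        s = report["separation"]
        lines.append(
            f"2-D separation: {s['misplaced_count']} misplaced {s['misplaced_ids']}"
        )
    if "som" in report:
        lines.append(f"SOM shared classes: {report['som']['shared_class_count']}")
    if "graph" in report:
        g = report["graph"]
        lines.append(f"{g['kind']}: {g['n_nodes']} nodes, {g['n_edges']} edges")
    return "\n".join(lines) + "\n"
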