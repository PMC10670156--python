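"""End-to-end analysis pipeline: model file -> STG -> topology -> reports.

`run_pipeline` ties together parsing, graph construction, topological
classification and trajectory enumeration, and writes a deterministic
bundle of artifacts (GraphML/DOT/TSV graph exports, topology JSON,
trajectory list and a text summary).  Repeated runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import export
from .dynamics import DEFAULT_MAX_STATES, UpdateMode, build_stg
from .parse import parse_model
from .topology import (
    DEFAULT_MAX_TRAJECTORIES,
    build_htg,
    classify_components,
    count_trajectories,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; every limit violation is an
    explicit error, never a silent truncation."""

    model_path: str
    mode: str = "asynchronous"
    max_states: int = DEFAULT_MAX_STATES
    max_trajectories: int = DEFAULT_MAX_TRAJECTORIES
    out_dir: str | None = None
    formats: tuple[str, ...] = ("graphml", "dot", "tsv", "json")
    ascii_only: bool = False
    branch_on_conflict: bool = False


@dataclass(frozen=True)
class PipelineResult:
    stg: object
    summary: object
    htg: object
    n_trajectories: int
    trajectories: tuple
    report: str
    files: tuple[Path, ...] = ()


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    text = Path(cfg.model_path).read_text(encoding="utf-8")
    model = parse_model(text)
    mode = UpdateMode.coerce(cfg.mode)
    stg = build_stg(model, mode, cfg.max_states, branch_on_conflict=cfg.branch_on_conflict)
    summary = classify_components(stg)
    htg = build_htg(stg, summary)
    n_traj, trajectories = count_trajectories(stg, summary, cfg.max_trajectories)
    report = export.topology_report(summary, n_traj, ascii_only=cfg.ascii_only)

    files: list[Path] = []
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stem = Path(cfg.model_path).stem + f".{mode.value}"
        writers = {
            "graphml": (f"{stem}.stg.graphml", export.stg_to_graphml(stg, cfg.ascii_only)),
            "dot": (f"{stem}.stg.dot", export.stg_to_dot(stg, cfg.ascii_only)),
            "tsv": (f"{stem}.stg.tsv", export.stg_to_tsv(stg, cfg.ascii_only)),
            "json": (f"{stem}.topology.json", summary.to_json(cfg.ascii_only)),
        }
        for fmt in cfg.formats:
            if fmt not in writers:
                raise ValueError(f"unknown export format {fmt!r}")
            name, content = writers[fmt]
            path = out / name
            path.write_text(content, encoding="utf-8")
            files.append(path)
        if "graphml" in cfg.formats:
            p = out / f"{stem}.htg.graphml"
            p.write_text(export.htg_to_graphml(summary, htg, cfg.ascii_only), encoding="utf-8")
            files.append(p)
        if "dot" in cfg.formats:
            p = out / f"{stem}.htg.dot"
            p.write_text(export.htg_to_dot(summary, htg, cfg.ascii_only), encoding="utf-8")
            files.append(p)
        arrow = "->" if cfg.ascii_only else "→"
        traj_lines = [
            t.render(stg, cfg.ascii_only)
            + "  ["
            + f"] {arrow} [".join(",".join(sorted(ls)) for ls in t.step_labels)
            + "]"
            if t.step_labels else t.render(stg, cfg.ascii_only)
            for t in trajectories
        ]
        p = out / f"{stem}.trajectories.txt"
        p.write_text("\n".join(traj_lines) + "\n", encoding="utf-8")
        files.append(p)
        p = out / f"{stem}.summary.txt"
        p.write_text(report, encoding="utf-8")
        files.append(p)

    return PipelineResult(stg, summary, htg, n_traj, tuple(trajectories), report, tuple(files))
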