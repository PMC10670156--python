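"""Exports: GraphML, DOT and TSV for STGs and hierarchical transition graphs.

State nodes are labeled with the canonical state string (present-variable
names for Boolean models, ``name=level`` pairs otherwise); edges carry the
comma-joined sorted rule labels.  All writers emit deterministic output:
sorted nodes, sorted edges, no timestamps.
"""

from __future__ import annotations

import io

import networkx as nx

from .dynamics import StateTransitionGraph
from .topology import HierarchicalTransitionGraph, TopologySummary

__all__ = [
    "stg_to_graphml",
    "stg_to_dot",
    "stg_to_tsv",
    "htg_to_graphml",
    "htg_to_dot",
    "topology_report",
]


def _render(g: StateTransitionGraph, ascii_only: bool):
    return lambda s: g.render_state(s, ascii_only=ascii_only)


def stg_to_graphml(g: StateTransitionGraph, ascii_only: bool = False) -> str:
    r = _render(g, ascii_only)
    out = nx.DiGraph()
    for s in sorted(g.states):
        out.add_node(r(s), state=r(s), initial=str(s in g.initial_states).lower())
    for t in g.transitions:
        out.add_edge(r(t.source), r(t.target), labels=",".join(sorted(t.labels)))
    buf = io.BytesIO()
    nx.write_graphml(out, buf, named_key_ids=True)
    return buf.getvalue().decode("utf-8")


def stg_to_dot(g: StateTransitionGraph, ascii_only: bool = False) -> str:
    r = _render(g, ascii_only)
    lines = ["digraph STG {", "  rankdir=TB;"]
    for s in sorted(g.states):
        shape = ', shape="doublecircle"' if s in g.deadlocks else ""
        lines.append(f'  "{r(s)}" [label="{r(s)}"{shape}];')
    for t in g.transitions:
        labels = ",".join(sorted(t.labels))
        lines.append(f'  "{r(t.source)}" -> "{r(t.target)}" [label="{labels}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def stg_to_tsv(g: StateTransitionGraph, ascii_only: bool = False) -> str:
    r = _render(g, ascii_only)
    lines = ["source\ttarget\tlabels"]
    for t in g.transitions:
        lines.append(f"{r(t.source)}\t{r(t.target)}\t{','.join(sorted(t.labels))}")
    return "\n".join(lines) + "\n"


def _htg_names(summary: TopologySummary, htg: HierarchicalTransitionGraph, ascii_only: bool):
    names = {}
    for c in htg.nodes:
        names[c] = f"{c.kind}:{summary.component_name(c, ascii_only=ascii_only)}"
    return names


def htg_to_graphml(
    summary: TopologySummary, htg: HierarchicalTransitionGraph, ascii_only: bool = False
) -> str:
    names = _htg_names(summary, htg, ascii_only)
    out = nx.DiGraph()
    for c in htg.nodes:
        out.add_node(names[c], kind=c.kind, size=len(c.members))
    for a, b in htg.edges:
        out.add_edge(names[a], names[b])
    buf = io.BytesIO()
    nx.write_graphml(out, buf, named_key_ids=True)
    return buf.getvalue().decode("utf-8")


def htg_to_dot(
    summary: TopologySummary, htg: HierarchicalTransitionGraph, ascii_only: bool = False
) -> str:
    names = _htg_names(summary, htg, ascii_only)
    shapes = {"deadlock": "doublecircle", "basin": "box", "cyclic_scc": "ellipse",
              "complex_scc": "octagon"}
    lines = ["digraph HTG {", "  rankdir=TB;"]
    for c in htg.nodes:
        lines.append(
            f'  "{names[c]}" [label="{names[c]} ({len(c.members)})", '
            f'shape="{shapes[c.kind]}"];'
        )
    for a, b in htg.edges:
        lines.append(f'  "{names[a]}" -> "{names[b]}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def topology_report(
    summary: TopologySummary, trajectories_count: int | None = None,
    ascii_only: bool = False,
) -> str:
    """Plain-text summary naming every component by its canonical member."""
    g = summary.stg
    r = _render(g, ascii_only)
    lines = [
        f"update mode: {g.mode.value}",
        f"states: {len(g.states)}  transitions: {len(g.transitions)}",
        f"deadlocks (stable states): {len(summary.deadlocks)}"
        + (": " + ", ".join("{%s}" % r(c.key) for c in summary.deadlocks)
           if summary.deadlocks else ""),
    ]
    transient = len(g.states) - sum(len(c.members) for c in summary.deadlocks)
    lines.append(f"transient states: {transient}")
    for c in summary.sccs:
        lines.append(
            f"{c.kind.replace('_', ' ')} {summary.component_name(c, ascii_only)}: "
            f"{len(c.members)} states"
        )
    for c in summary.basins:
        strength = "strong, fate determined" if c.is_strong_basin else "indeterminate fate"
        members = ", ".join("{%s}" % r(s) for s in sorted(c.members))
        lines.append(
            f"basin {summary.component_name(c, ascii_only)} ({strength}): "
            f"{members} -> attractors {sorted(c.attractor_key)}"
        )
    if trajectories_count is not None:
        lines.append(f"maximal trajectories from initial state(s): {trajectories_count}")
    return "\n".join(lines) + "\n"
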