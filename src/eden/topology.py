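"""Topological analysis of a state-transition graph.

Three structures summarize the long-run behavior of a qualitative model:

* **deadlock** (stable state) — a single state with no successor;
* **strongly connected component (SCC)** — a maximal set of mutually
  reachable states, i.e. a region where every change is reversible.
  A non-trivial SCC is *cyclic* when its induced sub-graph is one
  directed cycle (the discrete analogue of a limit cycle) and *complex*
  otherwise (several interleaved feedback loops);
* **basin** — a maximal set of transient states (outside every
  non-trivial SCC and deadlock) that all reach exactly the same set of
  terminal components.  A basin whose attractor key is a single terminal
  component is *strong*: its fate is determined.

Collapsing these components and keeping only the edges that cross
between them yields the *hierarchical transition graph* (HTG), an
acyclic summary in which every edge is an irreversible change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator

import networkx as nx

from .dynamics import StateTransitionGraph
from .model import ModelError, State

__all__ = [
    "Component",
    "TopologySummary",
    "HierarchicalTransitionGraph",
    "TrajectoryLimitError",
    "find_sccs",
    "classify_components",
    "build_htg",
    "count_trajectories",
]

DEFAULT_MAX_TRAJECTORIES = 100_000


class TrajectoryLimitError(ModelError):
    def __init__(self, cap: int):
        super().__init__(
            f"more than {cap} maximal trajectories; raise the cap to enumerate them all"
        )
        self.cap = cap


@dataclass(frozen=True)
class Component:
    """One node of the hierarchical transition graph.

    ``attractor_key`` is empty except for basins, where it holds the
    canonical keys of the terminal components every member reaches.
    """

    kind: str  # cyclic_scc | complex_scc | deadlock | basin
    members: frozenset[State]
    attractor_key: frozenset[str] = frozenset()

    @property
    def key(self) -> State:
        """Canonical smallest member state; names the component in reports."""
        return min(self.members)

    @property
    def is_strong_basin(self) -> bool:
        return self.kind == "basin" and len(self.attractor_key) == 1

    def sort_key(self) -> tuple:
        return (self.kind, self.key)


@dataclass(frozen=True)
class TopologySummary:
    """The full component classification of an STG."""

    stg: StateTransitionGraph
    components: tuple[Component, ...]

    @property
    def deadlocks(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.kind == "deadlock")

    @property
    def sccs(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.kind.endswith("_scc"))

    @property
    def basins(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.kind == "basin")

    @property
    def terminal_components(self) -> tuple[Component, ...]:
        term = []
        g = self.stg.to_networkx()
        for c in self.components:
            if c.kind == "deadlock":
                term.append(c)
            elif c.kind.endswith("_scc"):
                if all(t in c.members for m in c.members for t in g.successors(m)):
                    term.append(c)
        return tuple(term)

    def component_of(self, s: State) -> Component:
        for c in self.components:
            if s in c.members:
                return c
        raise KeyError(s)

    def component_name(self, c: Component, ascii_only: bool = False) -> str:
        return "{%s}" % self.stg.render_state(c.key, ascii_only=ascii_only)

    def to_json(self, ascii_only: bool = False) -> str:
        render = lambda s: self.stg.render_state(s, ascii_only=ascii_only)
        obj = [
            {
                "kind": c.kind,
                "members": sorted(render(s) for s in c.members),
                "attractor_key": sorted(c.attractor_key),
                "strong": c.is_strong_basin,
            }
            for c in sorted(self.components, key=Component.sort_key)
        ]
        return json.dumps(obj, indent=2, ensure_ascii=ascii_only)


@dataclass(frozen=True)
class HierarchicalTransitionGraph:
    """Acyclic condensation of an STG into its topological components."""

    nodes: tuple[Component, ...]
    edges: tuple[tuple[Component, Component], ...]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in self.nodes:
            g.add_node(c, kind=c.kind, size=len(c.members))
        g.add_edges_from(self.edges)
        return g


def find_sccs(g: StateTransitionGraph) -> list[frozenset[State]]:
    """All maximal SCCs in deterministic order (trivial singletons included).

    A singleton is a trivial SCC; self-loops cannot occur (enabledness is
    effect-bearing), so every singleton here is trivial.
    """
    nxg = g.to_networkx()
    sccs = [frozenset(c) for c in nx.strongly_connected_components(nxg)]
    return sorted(sccs, key=min)


def _is_cyclic_scc(members: frozenset[State], nxg: nx.DiGraph) -> bool:
    """A non-trivial SCC is cyclic iff every member has exactly one internal
    successor and one internal predecessor."""
    return all(
        sum(1 for t in nxg.successors(m) if t in members) == 1
        and sum(1 for t in nxg.predecessors(m) if t in members) == 1
        for m in members
    )


def classify_components(g: StateTransitionGraph) -> TopologySummary:
    """Partition every state into a deadlock, non-trivial SCC, or basin.

    Basins group transient states that lead to the same SCCs and stable
    states: the grouping key is the set of *all* reachable non-trivial
    SCCs and deadlocks, which guarantees the condensation stays acyclic
    even around non-terminal SCCs.  The exposed ``attractor_key`` is its
    terminal part (deadlocks plus terminal SCCs) — the possible fates of
    the basin; a singleton marks a strong basin.  Non-terminal SCCs
    remain their own components and never join basins.
    """
    nxg = g.to_networkx()
    components: list[Component] = []
    state_home: dict[State, Component] = {}

    for members in find_sccs(g):
        if len(members) > 1:
            kind = "cyclic_scc" if _is_cyclic_scc(members, nxg) else "complex_scc"
            c = Component(kind, members)
            components.append(c)
            for s in members:
                state_home[s] = c
    for s in g.states:
        if s not in state_home and nxg.out_degree(s) == 0:
            c = Component("deadlock", frozenset({s}))
            components.append(c)
            state_home[s] = c

    # every deadlock / non-trivial SCC, flagged terminal when inescapable
    named: dict[Component, tuple[str, bool]] = {}
    for c in components:
        name = "{%s}" % g.render_state(c.key)
        is_terminal = c.kind == "deadlock" or all(
            t in c.members for m in c.members for t in nxg.successors(m)
        )
        named[c] = (name, is_terminal)

    # per-state reachable components (reverse closure from each component)
    reach_all: dict[State, set[str]] = {s: set() for s in g.states}
    reach_terminal: dict[State, set[str]] = {s: set() for s in g.states}
    rev = nxg.reverse(copy=False)
    for c, (name, is_terminal) in named.items():
        touched: set[State] = set()
        for seed in c.members:
            touched.add(seed)
            touched.update(nx.descendants(rev, seed))
        for s in touched:
            reach_all[s].add(name)
            if is_terminal:
                reach_terminal[s].add(name)

    transient = sorted(s for s in g.states if s not in state_home)
    basins: dict[frozenset[str], set[State]] = {}
    for s in transient:
        basins.setdefault(frozenset(reach_all[s]), set()).add(s)
    for _, members in sorted(basins.items(), key=lambda kv: min(kv[1])):
        attractors = frozenset(reach_terminal[min(members)])
        components.append(Component("basin", frozenset(members), attractors))

    summary = TopologySummary(g, tuple(sorted(components, key=Component.sort_key)))
    assert sum(len(c.members) for c in summary.components) == len(g.states)
    return summary


def build_htg(g: StateTransitionGraph, summary: TopologySummary | None = None) -> HierarchicalTransitionGraph:
    """Merge components; keep an edge C1->C2 iff some state transition
    crosses from C1 to C2.  The result is acyclic by construction."""
    if summary is None:
        summary = classify_components(g)
    home = {s: c for c in summary.components for s in c.members}
    edges: set[tuple[Component, Component]] = set()
    for t in g.transitions:
        c1, c2 = home[t.source], home[t.target]
        if c1 is not c2:
            edges.add((c1, c2))
    nodes = tuple(sorted(summary.components, key=Component.sort_key))
    htg = HierarchicalTransitionGraph(
        nodes, tuple(sorted(edges, key=lambda e: (e[0].sort_key(), e[1].sort_key())))
    )
    if not nx.is_directed_acyclic_graph(htg.to_networkx()):
        raise AssertionError("hierarchical transition graph is cyclic — internal error")
    return htg


@dataclass(frozen=True)
class Trajectory:
    """A maximal path: states visited plus the rule labels of each step."""

    states: tuple[State, ...]
    step_labels: tuple[frozenset[str], ...]

    def render(self, g: StateTransitionGraph, ascii_only: bool = False) -> str:
        arrow = "->" if ascii_only else "→"
        return arrow.join("{%s}" % g.render_state(s, ascii_only=ascii_only) for s in self.states)


def _maximal_paths(
    nxg: nx.DiGraph, start: State, cap: int
) -> Iterator[tuple[State, ...]]:
    """DFS enumeration of maximal simple paths from ``start`` in a DAG."""
    stack: list[tuple[State, ...]] = [(start,)]
    emitted = 0
    while stack:
        path = stack.pop()
        succ = sorted(nxg.successors(path[-1]), reverse=True)
        if not succ:
            emitted += 1
            if emitted > cap:
                raise TrajectoryLimitError(cap)
            yield path
            continue
        for t in succ:
            stack.append(path + (t,))


def count_trajectories(
    g: StateTransitionGraph,
    summary: TopologySummary | None = None,
    max_trajectories: int = DEFAULT_MAX_TRAJECTORIES,
) -> tuple[int, list[Trajectory]]:
    """Alternative maximal trajectories from the initial state(s).

    For an acyclic STG these are the distinct maximal simple state paths
    from each initial state (ending in deadlocks), with per-step rule
    labels.  When the STG has cycles, trajectories are counted on the
    HTG — which is always acyclic — starting from the components holding
    initial states; each step then carries the union of the labels of
    the crossing transitions.
    """
    if summary is None:
        summary = classify_components(g)
    nxg = g.to_networkx()
    trajectories: list[Trajectory] = []

    if nx.is_directed_acyclic_graph(nxg):
        seen: set[tuple[State, ...]] = set()
        for init in sorted(g.initial_states):
            for path in _maximal_paths(nxg, init, max_trajectories):
                if path in seen:
                    continue
                seen.add(path)
                labels = tuple(
                    g.edge_labels(a, b) for a, b in zip(path, path[1:])
                )
                trajectories.append(Trajectory(path, labels))
                if len(trajectories) > max_trajectories:
                    raise TrajectoryLimitError(max_trajectories)
        trajectories.sort(key=lambda t: t.states)
        return len(trajectories), trajectories

    htg = build_htg(g, summary)
    hg = htg.to_networkx()
    home = {s: c for c in summary.components for s in c.members}
    crossing: dict[tuple[Component, Component], set[str]] = {}
    for t in g.transitions:
        c1, c2 = home[t.source], home[t.target]
        if c1 is not c2:
            crossing.setdefault((c1, c2), set()).update(t.labels)
    start_components = sorted({home[s] for s in g.initial_states}, key=Component.sort_key)
    seen_paths: set[tuple[Component, ...]] = set()
    for start in start_components:
        stack: list[tuple[Component, ...]] = [(start,)]
        while stack:
            path = stack.pop()
            succ = sorted(hg.successors(path[-1]), key=Component.sort_key, reverse=True)
            if not succ:
                if path not in seen_paths:
                    seen_paths.add(path)
                    states = tuple(c.key for c in path)
                    labels = tuple(
                        frozenset(crossing[(a, b)]) for a, b in zip(path, path[1:])
                    )
                    trajectories.append(Trajectory(states, labels))
                    if len(trajectories) > max_trajectories:
                        raise TrajectoryLimitError(max_trajectories)
                continue
            for t in succ:
                stack.append(path + (t,))
    trajectories.sort(key=lambda t: t.states)
    return len(trajectories), trajectories
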