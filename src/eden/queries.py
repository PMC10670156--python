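"""Model-checking query patterns over a computed state-transition graph.

Rather than a general temporal-logic interface, a fixed set of named
patterns covers the questions practitioners ask of qualitative ecosystem
models: is a state of interest *reachable*?  does a property hold
*invariantly*?  is an undesired outcome *avoidable*?  can the system
*stabilize inside* a region?  and is a particular event (rule) a
*necessary* or *sufficient* condition for an outcome?

Verdicts come with witnesses: a path through the graph proving the
verdict (or a counterexample path refuting the queried property).
Maximal paths are interpreted without fairness assumptions — a
trajectory that enters a cycle may stay there forever, so lasso-shaped
counterexamples are valid and are reported with their cycle appended
once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx

from .dynamics import StateTransitionGraph
from .model import ConditionAtom, ModelError, ModelSpec, State
from .topology import TopologySummary, classify_components

__all__ = [
    "StatePredicate",
    "QueryResult",
    "PredicateError",
    "parse_predicate",
    "reachable",
    "invariantly",
    "avoidable",
    "stable_in",
    "event_precedes",
    "event_suffices",
]


class PredicateError(ModelError):
    """A predicate references unknown variables or has bad syntax."""


class StatePredicate:
    """A Boolean-valued function of states, closed under and/or/not.

    Built from threshold atoms (``T = 1``), explicit state sets, or the
    connectives ``&``, ``|`` and ``~``.
    """

    def __init__(self, fn: Callable[[State], bool], description: str,
                 variables: frozenset[str] = frozenset()):
        self._fn = fn
        self.description = description
        self.variables = variables

    def __call__(self, s: State) -> bool:
        return self._fn(s)

    def __and__(self, other: "StatePredicate") -> "StatePredicate":
        return StatePredicate(
            lambda s: self(s) and other(s),
            f"({self.description} and {other.description})",
            self.variables | other.variables,
        )

    def __or__(self, other: "StatePredicate") -> "StatePredicate":
        return StatePredicate(
            lambda s: self(s) or other(s),
            f"({self.description} or {other.description})",
            self.variables | other.variables,
        )

    def __invert__(self) -> "StatePredicate":
        return StatePredicate(lambda s: not self(s), f"not {self.description}", self.variables)

    @classmethod
    def atom(cls, variable: str, op: str, level: int) -> "StatePredicate":
        a = ConditionAtom(variable, op, level)
        return cls(a.holds, f"{variable} {op} {level}", frozenset({variable}))

    @classmethod
    def of_states(cls, states: Iterable[State]) -> "StatePredicate":
        pool = frozenset(states)
        desc = "{" + " | ".join(str(s) for s in sorted(pool)) + "}"
        return cls(lambda s: s in pool, desc)

    def check_variables(self, model: ModelSpec) -> None:
        unknown = self.variables - set(model.variable_map)
        if unknown:
            raise PredicateError(f"predicate references unknown variables {sorted(unknown)}")

    def __repr__(self) -> str:
        return f"StatePredicate({self.description})"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op>>=|<=|>|<|=)"
    r"|(?P<int>-?\d+)|(?P<word>[A-Za-z_][A-Za-z0-9_]*[+-]?)|(?P<bad>\S))"
)


def parse_predicate(expr: str, model: ModelSpec | None = None) -> StatePredicate:
    """Parse ``"T=1 and not (A+ or P+)"`` into a :class:`StatePredicate`.

    Precedence: ``not`` binds tighter than ``and``, which binds tighter
    than ``or``.  Atoms use the model-file syntax (including Boolean
    ``+``/``-`` sugar).
    """
    expr = expr.replace("−", "-").replace("≥", ">=").replace("≤", "<=")
    tokens: list[tuple[str, str]] = []
    for m in _TOKEN_RE.finditer(expr):
        kind = m.lastgroup
        if kind == "bad":
            raise PredicateError(f"unexpected character {m.group()!r} in predicate {expr!r}")
        tokens.append((kind, m.group().strip()))
    pos = 0

    def peek() -> tuple[str, str] | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> tuple[str, str]:
        nonlocal pos
        if pos >= len(tokens):
            raise PredicateError(f"unexpected end of predicate {expr!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> StatePredicate:
        left = parse_and()
        while peek() and peek()[1] == "or":
            take()
            left = left | parse_and()
        return left

    def parse_and() -> StatePredicate:
        left = parse_not()
        while peek() and peek()[1] == "and":
            take()
            left = left & parse_not()
        return left

    def parse_not() -> StatePredicate:
        if peek() and peek()[1] == "not":
            take()
            return ~parse_not()
        return parse_primary()

    def parse_primary() -> StatePredicate:
        kind, value = take()
        if kind == "lpar":
            inner = parse_or()
            k, _ = take()
            if k != "rpar":
                raise PredicateError(f"missing ')' in predicate {expr!r}")
            return inner
        if kind == "word":
            if value.endswith(("+", "-")):
                return StatePredicate.atom(value[:-1], "=", 1 if value[-1] == "+" else 0)
            nxt = peek()
            if nxt and nxt[0] == "op":
                _, op = take()
                k, lvl = take()
                if k != "int":
                    raise PredicateError(f"expected a level after {value}{op} in {expr!r}")
                return StatePredicate.atom(value, op, int(lvl))
            raise PredicateError(f"bare variable {value!r} needs +/- or a comparison")
        raise PredicateError(f"unexpected token {value!r} in predicate {expr!r}")

    if not tokens:
        raise PredicateError("empty predicate")
    result = parse_or()
    if pos != len(tokens):
        raise PredicateError(f"trailing tokens after position {pos} in predicate {expr!r}")
    if model is not None:
        result.check_variables(model)
    return result


@dataclass(frozen=True)
class QueryResult:
    """Verdict plus an optional witness path (states and step labels)."""

    verdict: bool
    witness_states: tuple[State, ...] = ()
    witness_labels: tuple[frozenset[str], ...] = ()

    def __bool__(self) -> bool:
        return self.verdict

    def render_witness(self, g: StateTransitionGraph, ascii_only: bool = False) -> str:
        arrow = "->" if ascii_only else "→"
        return arrow.join(
            "{%s}" % g.render_state(s, ascii_only=ascii_only) for s in self.witness_states
        )


def _as_predicate(p: StatePredicate | str, model: ModelSpec) -> StatePredicate:
    if isinstance(p, str):
        return parse_predicate(p, model)
    p.check_variables(model)
    return p


def _path_result(g: StateTransitionGraph, path: list[State]) -> QueryResult:
    labels = tuple(g.edge_labels(a, b) for a, b in zip(path, path[1:]))
    return QueryResult(True, tuple(path), labels)


def _shortest_path_to(
    g: StateTransitionGraph, targets: set[State], *, sources: set[State] | None = None,
    nxg: nx.DiGraph | None = None,
) -> list[State] | None:
    """Deterministic BFS: shortest path, ties broken by canonical order."""
    if nxg is None:
        nxg = g.to_networkx()
    sources = set(g.initial_states) if sources is None else sources
    frontier = sorted(sources)
    parent: dict[State, State | None] = {s: None for s in frontier}
    while frontier:
        hits = sorted(s for s in frontier if s in targets)
        if hits:
            path: list[State] = []
            cur: State | None = hits[0]
            while cur is not None:
                path.append(cur)
                cur = parent[cur]
            return list(reversed(path))
        nxt: list[State] = []
        for s in frontier:
            for t in sorted(nxg.successors(s)):
                if t not in parent:
                    parent[t] = s
                    nxt.append(t)
        frontier = sorted(set(nxt))
    return None


def reachable(g: StateTransitionGraph, p: StatePredicate | str) -> QueryResult:
    """Is some state satisfying ``p`` reachable from an initial state?

    Witness: one shortest such path (empty when an initial state already
    satisfies ``p``)."""
    p = _as_predicate(p, g.model)
    targets = {s for s in g.states if p(s)}
    path = _shortest_path_to(g, targets)
    if path is None:
        return QueryResult(False)
    if len(path) == 1 and path[0] in g.initial_states:
        return QueryResult(True, (path[0],), ())
    return _path_result(g, path)


def invariantly(g: StateTransitionGraph, p: StatePredicate | str) -> QueryResult:
    """Does every reachable state satisfy ``p``?

    When false the witness is a shortest path to a violating state."""
    p = _as_predicate(p, g.model)
    violating = {s for s in g.states if not p(s)}
    if not violating:
        return QueryResult(True)
    path = _shortest_path_to(g, violating)
    assert path is not None  # every state in g is reachable
    res = _path_result(g, path)
    return QueryResult(False, res.witness_states, res.witness_labels)


def _restricted(g: StateTransitionGraph, keep: Callable[[State], bool]) -> nx.DiGraph:
    h = nx.DiGraph()
    h.add_nodes_from(s for s in g.states if keep(s))
    for t in g.transitions:
        if keep(t.source) and keep(t.target):
            h.add_edge(t.source, t.target)
    return h


def _maximal_endpoints(g: StateTransitionGraph, h: nx.DiGraph) -> tuple[set[State], set[State]]:
    """States in ``h`` where a maximal trajectory can end or persist:
    original deadlocks, and states on cycles of ``h`` (loop forever)."""
    deadlocks = {s for s in g.deadlocks if h.has_node(s)}
    on_cycle = {s for scc in nx.strongly_connected_components(h) if len(scc) > 1 for s in scc}
    return deadlocks, on_cycle


def avoidable(g: StateTransitionGraph, p: StatePredicate | str) -> QueryResult:
    """Can the system run forever (or stop) without ever entering ``p``?

    True iff some maximal trajectory from an initial state never visits
    a ``p``-state: a path through non-``p`` states to a deadlock, or to
    a cycle it may stay in (no fairness imposed).  Witness: such a
    trajectory, with any cycle appended once."""
    p = _as_predicate(p, g.model)
    h = _restricted(g, lambda s: not p(s))
    sources = {s for s in g.initial_states if h.has_node(s)}
    if not sources:
        return QueryResult(False)
    deadlocks, on_cycle = _maximal_endpoints(g, h)
    path = _shortest_path_to(g, deadlocks | on_cycle, sources=sources, nxg=h)
    if path is None:
        return QueryResult(False)
    if path[-1] in on_cycle and path[-1] not in deadlocks:
        path = path + _cycle_once(h, path[-1])
    return _path_result(g, path)


def _cycle_once(h: nx.DiGraph, start: State) -> list[State]:
    """One pass around a cycle of ``h`` through ``start`` (lasso tail)."""
    scc = next(c for c in nx.strongly_connected_components(h) if start in c)
    sub = h.subgraph(scc)
    ring = nx.shortest_path(sub, min(sub.successors(start)), start)
    return ring


def stable_in(g: StateTransitionGraph, p: StatePredicate | str,
              summary: TopologySummary | None = None) -> QueryResult:
    """Can the system settle permanently inside ``p``?

    True iff some reachable terminal component (deadlock or terminal
    SCC) lies entirely within ``p``; witness: a path into it."""
    p = _as_predicate(p, g.model)
    if summary is None:
        summary = classify_components(g)
    for c in sorted(summary.terminal_components, key=lambda c: c.sort_key()):
        if all(p(s) for s in c.members):
            path = _shortest_path_to(g, set(c.members))
            assert path is not None
            return _path_result(g, path)
    return QueryResult(False)


def _check_label(g: StateTransitionGraph, label: str) -> None:
    if not any(r.label == label for r in g.model.rules):
        raise ModelError(f"unknown rule label {label!r}")


def event_precedes(g: StateTransitionGraph, label: str, p: StatePredicate | str) -> QueryResult:
    """Necessity: must every route from an initial state into ``p`` pass
    through a transition firing ``label``?

    False when ``p`` can be reached with all ``label``-transitions
    removed; the witness is such a bypassing path (empty when an initial
    state already satisfies ``p``)."""
    _check_label(g, label)
    p = _as_predicate(p, g.model)
    targets = {s for s in g.states if p(s)}
    if _shortest_path_to(g, targets) is None:
        # p unreachable: necessity holds vacuously
        return QueryResult(True)
    h = g.to_networkx()
    h.remove_edges_from([
        (t.source, t.target) for t in g.transitions if label in t.labels
    ])
    path = _shortest_path_to(g, targets, nxg=h)
    if path is None:
        return QueryResult(True)
    res = _path_result(g, path) if len(path) > 1 else QueryResult(True, tuple(path), ())
    return QueryResult(False, res.witness_states, res.witness_labels)


def event_suffices(g: StateTransitionGraph, label: str, p: StatePredicate | str) -> QueryResult:
    """Sufficiency: does every maximal trajectory that fires ``label``
    visit a ``p``-state at some time?

    A counterexample is a maximal trajectory containing a ``label``
    transition but no ``p``-state: a path through non-``p`` states that
    crosses a ``label`` edge and then reaches a deadlock or a cycle it
    may stay in."""
    _check_label(g, label)
    p = _as_predicate(p, g.model)
    h = _restricted(g, lambda s: not p(s))
    sources = {s for s in g.initial_states if h.has_node(s)}
    if not sources:
        return QueryResult(True)
    label_edges = sorted(
        (t.source, t.target) for t in g.transitions
        if label in t.labels and h.has_edge(t.source, t.target)
    )
    deadlocks, on_cycle = _maximal_endpoints(g, h)
    for src, tgt in label_edges:
        prefix = _shortest_path_to(g, {src}, sources=sources, nxg=h)
        if prefix is None:
            continue
        suffix = _shortest_path_to(g, deadlocks | on_cycle, sources={tgt}, nxg=h)
        if suffix is None:
            continue
        path = prefix + suffix
        if path[-1] in on_cycle and path[-1] not in deadlocks:
            path = path + _cycle_once(h, path[-1])
        res = _path_result(g, path)
        return QueryResult(False, res.witness_states, res.witness_labels)
    return QueryResult(True)
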