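"""Possibilistic execution engine and state-transition-graph construction.

Two update modes are supported:

* **asynchronous** — exactly one enabled rule fires per transition.  A
  single rule may still assign several variables at once, which makes
  this the *partially synchronous* scheduling of rule-based qualitative
  models: events are serialized, but one event can move several
  variables together.
* **synchronous** — all enabled rules fire simultaneously in a single
  transition; the dynamics are deterministic (out-degree at most one)
  unless two enabled rules write different levels to the same variable,
  which is a conflict.

Enabledness is *effect-bearing*: a rule whose condition holds but whose
realization would leave the state unchanged is not enabled.  Hence the
graphs contain no self-loops and a deadlock is exactly a state with no
enabled rule.

Exploration is exhaustive (possibilistic): every trajectory compatible
with the rules is represented, with no probabilities, priorities or
timing.  States are expanded in canonical sorted order and rules tried
in label order, so rebuilding a graph is byte-identical across runs.
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .model import ModelError, ModelSpec, Rule, State

__all__ = [
    "UpdateMode",
    "Transition",
    "StateTransitionGraph",
    "SynchronousConflictError",
    "StateSpaceLimitError",
    "enabled_rules",
    "fire_rule",
    "successors",
    "build_stg",
]

DEFAULT_MAX_STATES = 1_000_000


class UpdateMode(str, enum.Enum):
    """Scheduling of enabled rules."""

    ASYNCHRONOUS = "asynchronous"
    SYNCHRONOUS = "synchronous"

    @classmethod
    def coerce(cls, value: "UpdateMode | str") -> "UpdateMode":
        if isinstance(value, cls):
            return value
        v = str(value).lower()
        for mode in cls:
            if mode.value.startswith(v) and v:
                return mode
        raise ValueError(f"unknown update mode {value!r}")


class SynchronousConflictError(ModelError):
    """Two simultaneously fired rules assign different levels to one variable."""

    def __init__(self, variable: str, rule_a: str, rule_b: str, state: State):
        super().__init__(
            f"synchronous conflict on variable {variable!r}: rules {rule_a} and "
            f"{rule_b} assign different levels in state {state}"
        )
        self.variable = variable
        self.rules = (rule_a, rule_b)
        self.state = state


class StateSpaceLimitError(ModelError):
    """Exploration exceeded max_states; the partial graph is not returned."""

    def __init__(self, max_states: int):
        super().__init__(
            f"state space exceeds max_states={max_states}; raise the limit to "
            f"explore further (exploration aborted, no partial result)"
        )
        self.max_states = max_states


@dataclass(frozen=True)
class Transition:
    """A merged labeled edge: all rules mapping ``source`` to ``target``."""

    source: State
    target: State
    labels: frozenset[str]

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ModelError("self-loop transition (enabledness must be effect-bearing)")
        if not self.labels:
            raise ModelError("transition without rule labels")


@dataclass(frozen=True)
class StateTransitionGraph:
    """Reachable states and merged labeled transitions under one update mode."""

    model: ModelSpec
    mode: UpdateMode
    states: frozenset[State]
    transitions: tuple[Transition, ...]
    initial_states: frozenset[State]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for s in sorted(self.states):
            g.add_node(s, initial=s in self.initial_states)
        for t in self.transitions:
            g.add_edge(t.source, t.target, labels=",".join(sorted(t.labels)))
        return g

    @property
    def deadlocks(self) -> frozenset[State]:
        """States with no outgoing transition (stable states)."""
        with_out = {t.source for t in self.transitions}
        return frozenset(s for s in self.states if s not in with_out)

    def successors_of(self, s: State) -> list[Transition]:
        return sorted((t for t in self.transitions if t.source == s),
                      key=lambda t: t.target)

    def edge_labels(self, source: State, target: State) -> frozenset[str]:
        for t in self.transitions:
            if t.source == source and t.target == target:
                return t.labels
        raise KeyError((source, target))

    def render_state(self, s: State, ascii_only: bool = False) -> str:
        return s.render(self.model, ascii_only=ascii_only)


def enabled_rules(m: ModelSpec, s: State) -> set[str]:
    """Labels of rules whose condition holds in ``s`` and whose realization
    changes ``s`` (effect-bearing enabledness)."""
    m.check_state(s)
    out: set[str] = set()
    for r in m.rules:
        if r.condition_holds(s) and any(s[var] != lvl for var, lvl in r.realization):
            out.add(r.label)
    return out


def fire_rule(m: ModelSpec, s: State, label: str) -> State:
    """Apply one enabled rule's realization atomically."""
    if label not in enabled_rules(m, s):
        raise ModelError(f"rule {label!r} is not enabled in state {s}")
    return s.apply(m.rule(label).assignments())


def _merged_assignment(rules: Iterable[Rule], s: State) -> dict[str, int]:
    """Union of realizations, checking pairwise write consistency."""
    merged: dict[str, int] = {}
    writer: dict[str, str] = {}
    for r in rules:
        for var, lvl in r.realization:
            if var in merged and merged[var] != lvl:
                raise SynchronousConflictError(var, writer[var], r.label, s)
            merged[var] = lvl
            writer.setdefault(var, r.label)
    return merged


def successors(
    m: ModelSpec,
    s: State,
    mode: UpdateMode | str,
    *,
    branch_on_conflict: bool = False,
) -> list[tuple[State, frozenset[str]]]:
    """Successor states of ``s`` with merged rule-label sets.

    Asynchronous: one entry per distinct target over all enabled rules.
    Synchronous: at most one entry — the union of all enabled realizations.
    A synchronous write conflict raises :class:`SynchronousConflictError`
    unless ``branch_on_conflict`` is set, in which case every maximal
    conflict-free subset of the enabled rules fires as its own branch
    (a documented extension, off by default).
    """
    mode = UpdateMode.coerce(mode)
    enabled = sorted(enabled_rules(m, s))
    if not enabled:
        return []
    if mode is UpdateMode.ASYNCHRONOUS:
        by_target: dict[State, set[str]] = {}
        for label in enabled:
            t = s.apply(m.rule(label).assignments())
            by_target.setdefault(t, set()).add(label)
        return sorted(
            ((t, frozenset(labels)) for t, labels in by_target.items()),
            key=lambda item: item[0],
        )
    # synchronous
    rules = [m.rule(label) for label in enabled]
    try:
        merged = _merged_assignment(rules, s)
    except SynchronousConflictError:
        if not branch_on_conflict:
            raise
        return _conflict_branches(m, s, enabled)
    target = s.apply(merged)
    if target == s:  # only possible with mutually cancelling writes
        return []
    return [(target, frozenset(enabled))]


def _conflict_branches(
    m: ModelSpec, s: State, enabled: list[str]
) -> list[tuple[State, frozenset[str]]]:
    """All maximal conflict-free subsets of the enabled rules, each fired
    synchronously as one branch."""
    conflict: set[frozenset[str]] = set()
    for a, b in combinations(enabled, 2):
        try:
            _merged_assignment([m.rule(a), m.rule(b)], s)
        except SynchronousConflictError:
            conflict.add(frozenset((a, b)))

    def is_free(subset: tuple[str, ...]) -> bool:
        return all(frozenset(p) not in conflict for p in combinations(subset, 2))

    free_subsets = [
        sub
        for k in range(len(enabled), 0, -1)
        for sub in combinations(enabled, k)
        if is_free(sub)
    ]
    maximal = [
        set(sub) for sub in free_subsets
        if not any(set(sub) < other for other in (set(x) for x in free_subsets))
    ]
    by_target: dict[State, set[str]] = {}
    for sub in maximal:
        target = s.apply(_merged_assignment([m.rule(x) for x in sorted(sub)], s))
        if target != s:
            by_target.setdefault(target, set()).update(sub)
    return sorted(
        ((t, frozenset(labels)) for t, labels in by_target.items()),
        key=lambda item: item[0],
    )


def build_stg(
    m: ModelSpec,
    mode: UpdateMode | str = UpdateMode.ASYNCHRONOUS,
    max_states: int = DEFAULT_MAX_STATES,
    *,
    branch_on_conflict: bool = False,
) -> StateTransitionGraph:
    """Exhaustive breadth-first closure of ``successors`` from the initial
    states: exactly the reachable states and all merged labeled transitions.

    Deterministic: states are dequeued in insertion (BFS) order with
    sorted tie-breaking at each expansion, so two runs produce identical
    graphs.  Exceeding ``max_states`` aborts with an explicit error.
    """
    mode = UpdateMode.coerce(mode)
    m.validated()
    for s in m.initial_states:
        m.check_state(s)

    initial = sorted(set(m.initial_states))
    seen: set[State] = set(initial)
    queue: deque[State] = deque(initial)
    transitions: list[Transition] = []
    while queue:
        s = queue.popleft()
        for target, labels in successors(m, s, mode, branch_on_conflict=branch_on_conflict):
            transitions.append(Transition(s, target, labels))
            if target not in seen:
                if len(seen) >= max_states:
                    raise StateSpaceLimitError(max_states)
                seen.add(target)
                queue.append(target)
    transitions.sort(key=lambda t: (t.source, t.target))
    return StateTransitionGraph(
        model=m,
        mode=mode,
        states=frozenset(seen),
        transitions=tuple(transitions),
        initial_states=frozenset(initial),
    )
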