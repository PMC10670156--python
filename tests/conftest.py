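"""Shared fixtures and an independent brute-force dynamics oracle.

The oracle re-evaluates rule conditions and realizations directly from
the model data structures, enumerating the *entire* state space rather
than exploring reachable states, so it shares no code path with the
engine's successor/closure logic.
"""

from __future__ import annotations

import itertools

import pytest
from hypothesis import settings

from eden import ModelSpec, State, apt_model, germination_models, toggle_model

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def apt() -> ModelSpec:
    return apt_model()


@pytest.fixture(scope="session")
def germ_bool() -> ModelSpec:
    return germination_models()[0]


@pytest.fixture(scope="session")
def germ_mv() -> ModelSpec:
    return germination_models()[1]


@pytest.fixture(scope="session")
def toggle() -> ModelSpec:
    return toggle_model()


# --- brute-force oracle -------------------------------------------------

_EVAL = {
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    "<": lambda a, b: a < b,
    "=": lambda a, b: a == b,
}


def oracle_enabled(model: ModelSpec, state: State) -> list:
    """Rules whose condition holds and whose realization changes the state."""
    sd = dict(state.assignment)
    out = []
    for r in model.rules:
        if all(_EVAL[a.op](sd[a.variable], a.level) for a in r.condition):
            if any(sd[v] != lvl for v, lvl in r.realization):
                out.append(r)
    return out


def oracle_apply(state: State, assignments) -> State:
    sd = dict(state.assignment)
    sd.update(assignments)
    return State(tuple(sd.items()))


def oracle_full_relation(model: ModelSpec, mode: str):
    """Transition relation over ALL states of the product domain.

    Returns (edges, conflict_states) where edges maps (src, tgt) to the
    set of labels, and conflict_states are the states in which the
    synchronous union of realizations is contradictory.
    """
    names = [v.name for v in model.variables]
    domains = [range(v.kmax + 1) for v in model.variables]
    edges: dict[tuple[State, State], set[str]] = {}
    conflicts: set[State] = set()
    for combo in itertools.product(*domains):
        s = State(tuple(zip(names, combo)))
        enabled = oracle_enabled(model, s)
        if not enabled:
            continue
        if mode == "asynchronous":
            for r in enabled:
                t = oracle_apply(s, dict(r.realization))
                if t != s:
                    edges.setdefault((s, t), set()).add(r.label)
        else:
            merged: dict[str, int] = {}
            bad = False
            for r in enabled:
                for v, lvl in r.realization:
                    if v in merged and merged[v] != lvl:
                        bad = True
                    merged[v] = lvl
            if bad:
                conflicts.add(s)
                continue
            t = oracle_apply(s, merged)
            if t != s:
                edges[(s, t)] = {r.label for r in enabled}
    return edges, conflicts


def oracle_reachable_graph(model: ModelSpec, mode: str):
    """Restrict the full relation to states reachable from the initial
    states.  Returns (states, edges, conflict_hit) where conflict_hit is
    True when synchronous exploration reaches a conflicting state."""
    edges, conflicts = oracle_full_relation(model, mode)
    succ: dict[State, list[State]] = {}
    for (a, b) in edges:
        succ.setdefault(a, []).append(b)
    seen = set(model.initial_states)
    frontier = list(seen)
    conflict_hit = False
    while frontier:
        s = frontier.pop()
        if s in conflicts:
            conflict_hit = True
        for t in succ.get(s, ()):
            if t not in seen:
                seen.add(t)
                frontier.append(t)
    kept = {(a, b): ls for (a, b), ls in edges.items() if a in seen}
    return seen, kept, conflict_hit


def oracle_reachable_terminals(model: ModelSpec, mode: str = "asynchronous"):
    """Per-state sets of reachable terminal structures, by pairwise
    reachability over the full relation (independent of the SCC code)."""
    states, edges, _ = oracle_reachable_graph(model, mode)
    succ: dict[State, set[State]] = {s: set() for s in states}
    for (a, b) in edges:
        succ[a].add(b)

    def descendants(s: State) -> set[State]:
        seen, stack = {s}, [s]
        while stack:
            x = stack.pop()
            for t in succ[x]:
                if t not in seen:
                    seen.add(t)
                    stack.append(t)
        return seen

    desc = {s: descendants(s) for s in states}
    # terminal structure of s: the set of states it can never leave again
    # deadlocks: no successors; terminal SCC: mutually reachable & closed
    terminal_of: dict[State, frozenset[State]] = {}
    for s in states:
        comp = frozenset(x for x in desc[s] if s in desc[x])  # SCC of s
        closed = all(t in comp for x in comp for t in succ[x])
        if closed:
            terminal_of[s] = comp
    reach_term = {
        s: frozenset(terminal_of[t] for t in desc[s] if t in terminal_of)
        for s in states
    }
    return reach_term, terminal_of
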