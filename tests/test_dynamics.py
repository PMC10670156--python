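"""Execution engine: enabledness, firing, successors, STG construction.

The reference values for the three-species disassembly model were
hand-traced from its four extinction rules and cross-checked by the
brute-force oracle in conftest, which enumerates the full product state
space independently of the engine.
"""

import pytest
from hypothesis import given, settings, strategies as st

from eden import (
    ModelError,
    StateSpaceLimitError,
    SynchronousConflictError,
    UpdateMode,
    build_stg,
    enabled_rules,
    fire_rule,
    parse_model,
    random_model,
    successors,
)

from conftest import oracle_reachable_graph


def _s(model, **levels):
    return model.state(**levels)


class TestEnabledRules:
    def test_full_community_enables_the_three_extinction_rules(self, apt):
        assert enabled_rules(apt, _s(apt, A=1, P=1, T=1)) == {"R1", "R2", "R3"}

    def test_lone_survivor_state_is_deadlocked(self, apt):
        assert enabled_rules(apt, _s(apt, T=1)) == set()

    def test_predator_without_prey_can_starve_or_eat(self, apt):
        assert enabled_rules(apt, _s(apt, A=1, T=1)) == {"R2", "R4"}

    def test_effect_bearing_no_op_rules_are_not_enabled(self, germ_mv):
        # at M=2 both seedlings present: conditions hold but nothing changes
        assert enabled_rules(germ_mv, _s(germ_mv, M=2, S1=1, S2=1)) == set()

    def test_multivalued_thresholds(self, germ_mv):
        assert enabled_rules(germ_mv, _s(germ_mv, M=1, S1=0, S2=1)) == {"R1", "R4"}

    def test_invalid_state_rejected(self, apt):
        from eden import State
        with pytest.raises(ModelError, match="not total"):
            enabled_rules(apt, State.from_mapping({"A": 1}))


class TestFireRule:
    def test_predation_removes_tetrahymena(self, apt):
        out = fire_rule(apt, _s(apt, A=1, P=1, T=1), "R2")
        assert out == _s(apt, A=1, P=1, T=0)

    def test_germination_step(self, germ_bool):
        out = fire_rule(germ_bool, _s(germ_bool, M=1, S=0), "R1")
        assert out == _s(germ_bool, M=1, S=1)

    def test_multi_variable_realization_is_atomic(self):
        m = parse_model(
            "variable X\nvariable Y\nvariable Z\n"
            "rule R1: X+ >> Y+, Z-\ninitial: X+, Z+\n"
        )
        out = fire_rule(m, m.state(X=1, Y=0, Z=1), "R1")
        assert out == m.state(X=1, Y=1, Z=0)

    def test_firing_a_disabled_rule_is_an_error(self, apt):
        with pytest.raises(ModelError, match="not enabled"):
            fire_rule(apt, _s(apt, T=1), "R1")


class TestSuccessors:
    def test_asynchronous_merges_alternative_rules_per_target(self, apt):
        succ = successors(apt, _s(apt, A=1, P=1, T=1), "asynchronous")
        as_map = {t: labels for t, labels in succ}
        assert as_map == {
            _s(apt, A=1, P=1, T=0): {"R2", "R3"},  # two routes to T's extinction
            _s(apt, A=1, P=0, T=1): {"R1"},
        }

    def test_deadlock_has_no_successors(self, apt):
        assert successors(apt, _s(apt, T=1), "asynchronous") == []

    def test_synchronous_fires_all_enabled_rules_at_once(self, apt):
        succ = successors(apt, _s(apt, A=1, P=1, T=1), "synchronous")
        assert succ == [(_s(apt, A=1, P=0, T=0), frozenset({"R1", "R2", "R3"}))]

    def test_synchronous_write_conflict_raises_naming_rules_and_variable(self):
        m = parse_model(
            "variable X\nvariable Y levels 0..2\n"
            "rule R1: X+ >> Y = 1\nrule R2: X+ >> Y = 2\ninitial: X+\n"
        )
        with pytest.raises(SynchronousConflictError) as exc:
            successors(m, m.state(X=1, Y=0), "synchronous")
        msg = str(exc.value)
        assert "'Y'" in msg and "R1" in msg and "R2" in msg

    def test_conflict_branching_extension_explores_maximal_subsets(self):
        m = parse_model(
            "variable X\nvariable Y levels 0..2\nvariable Z\n"
            "rule R1: X+ >> Y = 1\nrule R2: X+ >> Y = 2\nrule R3: X+ >> Z+\n"
            "initial: X+\n"
        )
        succ = successors(m, m.state(X=1, Y=0), "synchronous", branch_on_conflict=True)
        as_map = {t: labels for t, labels in succ}
        # maximal conflict-free subsets: {R1,R3} and {R2,R3}
        assert as_map == {m.state(X=1, Y=1, Z=1): {"R1", "R3"},
                          m.state(X=1, Y=2, Z=1): {"R2", "R3"}}


class TestBuildStg:
    def test_apt_asynchronous_graph_matches_the_published_facts(self, apt):
        g = build_stg(apt, "asynchronous")
        assert len(g.states) == 6
        assert len(g.transitions) == 6
        deadlocks = {g.render_state(s) for s in g.deadlocks}
        assert deadlocks == {"T", "∅"}
        edges = {(g.render_state(t.source), g.render_state(t.target)) for t in g.transitions}
        assert edges == {
            ("APT", "AP"), ("APT", "AT"), ("AP", "A"),
            ("AT", "A"), ("AT", "T"), ("A", "∅"),
        }
        assert g.edge_labels(_s(apt, A=1, P=1, T=1), _s(apt, A=1, P=1, T=0)) == {"R2", "R3"}

    def test_apt_synchronous_collapse_is_a_three_state_path(self, apt):
        g = build_stg(apt, "synchronous")
        assert len(g.states) == 3
        assert {g.render_state(s) for s in g.deadlocks} == {"∅"}
        # deterministic: out-degree <= 1 everywhere
        sources = [t.source for t in g.transitions]
        assert len(sources) == len(set(sources))

    def test_zero_rule_model_yields_single_state_graph(self):
        m = parse_model("variable A\ninitial: A+\n")
        g = build_stg(m, "asynchronous")
        assert len(g.states) == 1 and len(g.transitions) == 0

    def test_max_states_overflow_is_an_explicit_error(self, apt):
        with pytest.raises(StateSpaceLimitError, match="max_states=3"):
            build_stg(apt, "asynchronous", max_states=3)

    def test_rebuild_is_identical(self, apt):
        assert build_stg(apt, "asynchronous") == build_stg(apt, "asynchronous")

    def test_boolean_germination_single_step(self, germ_bool):
        g = build_stg(germ_bool, "asynchronous")
        assert len(g.states) == 2 and len(g.transitions) == 1

    def test_synchronous_endpoint_is_an_asynchronous_deadlock(self, apt):
        sync = build_stg(apt, "synchronous")
        async_ = build_stg(apt, "asynchronous")
        (endpoint,) = sync.deadlocks
        assert endpoint in async_.deadlocks


@settings(max_examples=40, deadline=None)
@given(
    n_vars=st.integers(1, 6),
    n_rules=st.integers(0, 10),
    seed=st.integers(0, 10_000),
    mode=st.sampled_from(["asynchronous", "synchronous"]),
)
def test_engine_agrees_with_brute_force_oracle(n_vars, n_rules, seed, mode):
    """Reachable STG == brute-force transition relation over all 2^n states."""
    m = random_model(n_vars, n_rules, seed)
    o_states, o_edges, o_conflict = oracle_reachable_graph(m, mode)
    try:
        g = build_stg(m, mode)
    except SynchronousConflictError:
        assert mode == "synchronous" and o_conflict
        return
    assert not o_conflict
    assert g.states == frozenset(o_states)
    engine_edges = {(t.source, t.target): set(t.labels) for t in g.transitions}
    assert engine_edges == o_edges


@settings(max_examples=40, deadline=None)
@given(
    n_vars=st.integers(1, 6),
    n_rules=st.integers(0, 10),
    seed=st.integers(0, 10_000),
)
def test_no_self_loops_and_labels_are_exact(n_vars, n_rules, seed):
    """(s,t) is an edge iff some enabled rule maps s to t; labels exact."""
    m = random_model(n_vars, n_rules, seed)
    g = build_stg(m, "asynchronous")
    for t in g.transitions:
        assert t.source != t.target
        realized = {
            label for label in enabled_rules(m, t.source)
            if fire_rule(m, t.source, label) == t.target
        }
        assert realized == set(t.labels)
    # completeness: every enabled firing appears as an edge
    for s in g.states:
        for label in enabled_rules(m, s):
            tgt = fire_rule(m, s, label)
            assert label in g.edge_labels(s, tgt)


def test_update_mode_coercion():
    assert UpdateMode.coerce("sync") is UpdateMode.SYNCHRONOUS
    assert UpdateMode.coerce(UpdateMode.ASYNCHRONOUS) is UpdateMode.ASYNCHRONOUS
    with pytest.raises(ValueError):
        UpdateMode.coerce("bogus")
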