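"""STG topology: SCCs, component classification, HTG, trajectories."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from eden import (
    build_htg,
    build_stg,
    classify_components,
    count_trajectories,
    cycle3_model,
    find_sccs,
    parse_model,
    random_model,
)

from conftest import oracle_reachable_terminals


@pytest.fixture(scope="module")
def apt_stg(apt):
    return build_stg(apt, "asynchronous")


@pytest.fixture(scope="module")
def toggle_stg(toggle):
    return build_stg(toggle, "asynchronous")


class TestSccs:
    def test_disassembly_graph_has_only_trivial_sccs(self, apt_stg):
        sccs = find_sccs(apt_stg)
        assert len(sccs) == 6
        assert all(len(c) == 1 for c in sccs)

    def test_toggle_oscillator_is_one_four_state_scc(self, toggle_stg):
        nontrivial = [c for c in find_sccs(toggle_stg) if len(c) > 1]
        assert len(nontrivial) == 1
        assert len(nontrivial[0]) == 4

    def test_single_state_graph_has_one_trivial_scc(self):
        g = build_stg(parse_model("variable A\ninitial: A+\n"))
        assert find_sccs(g) == [frozenset(g.states)]


class TestClassification:
    def test_disassembly_components(self, apt_stg):
        s = classify_components(apt_stg)
        assert {apt_stg.render_state(c.key) for c in s.deadlocks} == {"T", "∅"}
        assert len(s.sccs) == 0
        basins = {
            frozenset(apt_stg.render_state(m) for m in c.members): c
            for c in s.basins
        }
        determined = basins[frozenset({"AP", "A"})]
        assert determined.attractor_key == {"{∅}"}
        assert determined.is_strong_basin
        undetermined = basins[frozenset({"APT", "AT"})]
        assert undetermined.attractor_key == {"{T}", "{∅}"}
        assert not undetermined.is_strong_basin

    def test_toggle_is_one_complex_scc_nothing_else(self, toggle_stg):
        s = classify_components(toggle_stg)
        assert [c.kind for c in s.components] == ["complex_scc"]
        assert len(s.components[0].members) == 4

    def test_three_cycle_is_cyclic(self):
        g = build_stg(cycle3_model())
        s = classify_components(g)
        assert [c.kind for c in s.components] == ["cyclic_scc"]

    def test_partition_covers_every_state_once(self, apt_stg, toggle_stg):
        for g in (apt_stg, toggle_stg):
            s = classify_components(g)
            counted = [m for c in s.components for m in c.members]
            assert sorted(counted) == sorted(g.states)


def test_basins_split_around_a_transient_scc_keeps_htg_acyclic():
    """Transient states before and after an escapable SCC share the same
    terminal fate but must land in different basins, or the condensation
    would contain a cycle (basin -> SCC -> basin)."""
    m = parse_model(
        "variable X levels 0..4\n"
        "rule R1: X = 0 >> X = 1\n"
        "rule R2: X = 1 >> X = 2\n"
        "rule R3: X = 2 >> X = 1\n"
        "rule R4: X = 2 >> X = 3\n"
        "rule R5: X = 0 >> X = 3\n"
        "rule R6: X = 3 >> X = 4\n"
        "initial: X = 0\n"
    )
    g = build_stg(m, "asynchronous")
    summary = classify_components(g)
    assert [c.kind for c in summary.sccs] == ["cyclic_scc"]  # {1,2}, escapable
    basins = summary.basins
    assert len(basins) == 2  # {X=0} upstream, {X=3} downstream
    assert all(c.attractor_key == frozenset({"{X=4}"}) for c in basins)
    assert all(c.is_strong_basin for c in basins)
    htg = build_htg(g, summary)
    assert nx.is_directed_acyclic_graph(htg.to_networkx())
    assert len(htg.nodes) == 4


class TestHtg:
    def test_disassembly_htg_nodes_and_edges(self, apt_stg):
        s = classify_components(apt_stg)
        htg = build_htg(apt_stg, s)
        assert len(htg.nodes) == 4
        named = {
            (a.kind, apt_stg.render_state(a.key),
             b.kind, apt_stg.render_state(b.key))
            for a, b in htg.edges
        }
        # components are named by their canonical (smallest) member state
        assert named == {
            ("basin", "AT", "basin", "A"),
            ("basin", "AT", "deadlock", "T"),
            ("basin", "A", "deadlock", "∅"),
        }

    def test_toggle_htg_is_a_single_node(self, toggle_stg):
        htg = build_htg(toggle_stg)
        assert len(htg.nodes) == 1 and len(htg.edges) == 0

    def test_single_state_htg(self):
        g = build_stg(parse_model("variable A\ninitial: A+\n"))
        htg = build_htg(g)
        assert len(htg.nodes) == 1 and htg.nodes[0].kind == "deadlock"


class TestTrajectories:
    def test_three_alternative_disassembly_sequences(self, apt_stg):
        n, trajs = count_trajectories(apt_stg)
        assert n == 3
        rendered = {t.render(apt_stg) for t in trajs}
        assert rendered == {
            "{APT}→{AP}→{A}→{∅}",
            "{APT}→{AT}→{A}→{∅}",
            "{APT}→{AT}→{T}",
        }
        # per-step rule labels carried along the merged edge
        by_render = {t.render(apt_stg): t for t in trajs}
        assert by_render["{APT}→{AP}→{A}→{∅}"].step_labels[0] == {"R2", "R3"}

    def test_synchronous_collapse_is_a_single_trajectory(self, apt):
        n, trajs = count_trajectories(build_stg(apt, "synchronous"))
        assert n == 1
        assert len(trajs[0].states) == 3

    def test_zero_rule_model_has_the_initial_trajectory_only(self):
        g = build_stg(parse_model("variable A\ninitial: A+\n"))
        n, trajs = count_trajectories(g)
        assert n == 1 and trajs[0].states == tuple(g.states)

    def test_cyclic_stg_counts_on_the_htg(self, toggle_stg):
        n, _ = count_trajectories(toggle_stg)
        assert n == 1  # single component, trivially one trajectory

    def test_trajectory_cap_is_an_explicit_error(self, apt_stg):
        from eden import TrajectoryLimitError
        with pytest.raises(TrajectoryLimitError):
            count_trajectories(apt_stg, max_trajectories=2)


@settings(max_examples=30, deadline=None)
@given(
    n_vars=st.integers(1, 6),
    n_rules=st.integers(0, 12),
    seed=st.integers(0, 10_000),
)
def test_sccs_match_pairwise_reachability_oracle(n_vars, n_rules, seed):
    g = build_stg(random_model(n_vars, n_rules, seed), "asynchronous")
    nxg = g.to_networkx()
    reach = {s: nx.descendants(nxg, s) | {s} for s in g.states}
    expected = set()
    for s in g.states:
        expected.add(frozenset(t for t in reach[s] if s in reach[t]))
    assert set(find_sccs(g)) == expected


@settings(max_examples=30, deadline=None)
@given(
    n_vars=st.integers(1, 6),
    n_rules=st.integers(0, 12),
    seed=st.integers(0, 10_000),
)
def test_htg_acyclic_partition_and_basin_keys_on_random_models(n_vars, n_rules, seed):
    m = random_model(n_vars, n_rules, seed)
    g = build_stg(m, "asynchronous")
    summary = classify_components(g)
    # partition
    counted = [s for c in summary.components for s in c.members]
    assert sorted(counted) == sorted(g.states)
    # acyclic condensation
    htg = build_htg(g, summary)
    assert nx.is_directed_acyclic_graph(htg.to_networkx())
    # basin coherence against per-state brute-force reachable terminal sets
    reach_term, _ = oracle_reachable_terminals(m, "asynchronous")
    for c in summary.components:
        if c.kind != "basin":
            continue
        member_keys = {
            frozenset("{%s}" % g.render_state(min(t)) for t in reach_term[s])
            for s in c.members
        }
        assert member_keys == {frozenset(c.attractor_key)}


@settings(max_examples=30, deadline=None)
@given(
    n_vars=st.integers(1, 6),
    n_rules=st.integers(0, 12),
    seed=st.integers(0, 10_000),
)
def test_cyclic_complex_dichotomy(n_vars, n_rules, seed):
    g = build_stg(random_model(n_vars, n_rules, seed), "asynchronous")
    nxg = g.to_networkx()
    for c in classify_components(g).sccs:
        degree_one = all(
            sum(1 for t in nxg.successors(m) if t in c.members) == 1
            and sum(1 for t in nxg.predecessors(m) if t in c.members) == 1
            for m in c.members
        )
        assert (c.kind == "cyclic_scc") == degree_one
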