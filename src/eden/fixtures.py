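"""Built-in example models and a seeded random-model generator.

The catalog regenerates, in code, the worked models used throughout the
documentation and tests:

``apt``
    Community disassembly of three protist species — *Amoeba proteus*
    (A), *Paramecium caudatum* (P) and *Tetrahymena pyriformis* (T) —
    driven by trophic and competitive interactions: A eats and depends
    on P; A eats T; P competes (unidirectionally) with T.  Each rule is
    an extinction event.  From the full community {APT} the asynchronous
    dynamics branch into three alternative disassembly trajectories
    ending in the two stable communities {T} and {∅}, while the
    synchronous dynamics are deterministic and collapse to {∅} only.

``germination_boolean`` / ``germination_multivalued``
    Seed germination gated by soil moisture.  The Boolean model has a
    single functionality threshold (moist/dry) driving one seedling
    variable; the multivalued model distinguishes three moisture levels
    (0, 1, 2) gating two species with different requirements.  Collapsing
    the levels to one threshold merges the two species into one: if
    moisture is sufficient for the least demanding species, the Boolean
    abstraction treats it as sufficient for all.

``toggle``
    A two-variable oscillator whose four reachable states are mutually
    reachable: one complex strongly connected component, no deadlock.

``cycle3``
    A single three-level variable stepped around 0→1→2→0: the minimal
    cyclic strongly connected component (discrete limit cycle).

``random_model``
    Seeded Boolean models for property tests: reproducible, always
    valid, with 1–3 condition atoms and 1–2 assignments per rule.
"""

from __future__ import annotations

import random

from .model import ConditionAtom, ModelSpec, Rule, State, VariableSpec

__all__ = [
    "apt_model",
    "germination_models",
    "toggle_model",
    "cycle3_model",
    "random_model",
    "CATALOG",
]


def _boolean_model(
    names: list[str],
    rules: list[Rule],
    initial: dict[str, int],
) -> ModelSpec:
    variables = tuple(VariableSpec(n) for n in names)
    assign = {n: 0 for n in names}
    assign.update(initial)
    return ModelSpec(variables, tuple(rules), (State.from_mapping(assign),)).validated()


def _present(var: str) -> ConditionAtom:
    return ConditionAtom(var, "=", 1)


def _absent(var: str) -> ConditionAtom:
    return ConditionAtom(var, "=", 0)


def apt_model() -> ModelSpec:
    """The three-species community-disassembly model (see module docs).

    Rules (extinction events):

    * R1 — A eats P: while both are present, P may go extinct.
    * R2 — A eats T: while both are present, T may go extinct.
    * R3 — P outcompetes T: while both are present, T may go extinct.
    * R4 — A depends on P: once P is gone, A starves.
    """
    rules = [
        Rule("R1", (_present("A"), _present("P")), (("P", 0),)),
        Rule("R2", (_present("A"), _present("T")), (("T", 0),)),
        Rule("R3", (_present("P"), _present("T")), (("T", 0),)),
        Rule("R4", (_present("A"), _absent("P")), (("A", 0),)),
    ]
    return _boolean_model(["A", "P", "T"], rules, {"A": 1, "P": 1, "T": 1})


def germination_models() -> tuple[ModelSpec, ModelSpec]:
    """(Boolean, multivalued) seed-germination models.

    Boolean: moisture M gates seedlings S via ``M+ >> S+`` and
    ``M- >> S-``.  Multivalued: M has levels 0..2 and two species
    S1, S2 germinate at thresholds 1 and 2 respectively, via four rules.
    """
    boolean = _boolean_model(
        ["M", "S"],
        [
            Rule("R1", (_present("M"),), (("S", 1),)),
            Rule("R2", (_absent("M"),), (("S", 0),)),
        ],
        {"M": 1},
    )
    mv_vars = (VariableSpec("M", 2), VariableSpec("S1"), VariableSpec("S2"))
    mv_rules = (
        Rule("R1", (ConditionAtom("M", ">=", 1),), (("S1", 1),)),
        Rule("R2", (ConditionAtom("M", ">=", 2),), (("S2", 1),)),
        Rule("R3", (ConditionAtom("M", "<", 1),), (("S1", 0),)),
        Rule("R4", (ConditionAtom("M", "<", 2),), (("S2", 0),)),
    )
    multivalued = ModelSpec(
        mv_vars, mv_rules,
        (State.from_mapping({"M": 1, "S1": 0, "S2": 0}),),
    ).validated()
    return boolean, multivalued


def toggle_model() -> ModelSpec:
    """Oscillating driver M with follower S; all four states recur."""
    rules = [
        Rule("T1", (_absent("M"),), (("M", 1),)),
        Rule("T2", (_present("M"),), (("M", 0),)),
        Rule("T3", (_present("M"),), (("S", 1),)),
        Rule("T4", (_absent("M"),), (("S", 0),)),
    ]
    return _boolean_model(["M", "S"], rules, {})


def cycle3_model() -> ModelSpec:
    """One variable with levels 0..2 stepped around a three-cycle."""
    rules = (
        Rule("K1", (ConditionAtom("C", "=", 0),), (("C", 1),)),
        Rule("K2", (ConditionAtom("C", "=", 1),), (("C", 2),)),
        Rule("K3", (ConditionAtom("C", "=", 2),), (("C", 0),)),
    )
    return ModelSpec(
        (VariableSpec("C", 2),), rules, (State.from_mapping({"C": 0}),)
    ).validated()


def random_model(n_vars: int, n_rules: int, seed: int) -> ModelSpec:
    """A reproducible random Boolean model for property testing.

    Conditions draw 1–3 distinct presence/absence atoms; realizations
    assign 1–2 variables.  Same seed, same model.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if n_rules < 0:
        raise ValueError("n_rules must be >= 0")
    rng = random.Random(seed)
    names = [f"V{i}" for i in range(n_vars)]
    rules = []
    for i in range(n_rules):
        cond_vars = rng.sample(names, k=rng.randint(1, min(3, n_vars)))
        condition = tuple(
            ConditionAtom(v, "=", rng.randint(0, 1)) for v in cond_vars
        )
        real_vars = rng.sample(names, k=rng.randint(1, min(2, n_vars)))
        realization = tuple((v, rng.randint(0, 1)) for v in real_vars)
        rules.append(Rule(f"R{i + 1}", condition, realization))
    initial = {n: rng.randint(0, 1) for n in names}
    return _boolean_model(names, rules, initial)


def _germination_boolean() -> ModelSpec:
    return germination_models()[0]


def _germination_multivalued() -> ModelSpec:
    return germination_models()[1]


#: Named fixture generators for the CLI (`eden fixtures <name>`).
CATALOG = {
    "apt": apt_model,
    "germination_boolean": _germination_boolean,
    "germination_multivalued": _germination_multivalued,
    "toggle": toggle_model,
    "cycle3": cycle3_model,
}
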