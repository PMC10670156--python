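"""Core domain types for qualitative discrete-event models.

A model is a set of discrete variables (Boolean or multivalued integer
levels 0..kmax), a set of labeled if-then rules, and one or more initial
states.  A rule has a *condition* (conjunction of threshold atoms such as
``M >= 1`` or the Boolean sugar ``M+``) and a *realization* (an atomic
assignment of new levels to one or more variables).  States are total
assignments of a level to every variable.

All variables are integer-leveled internally; the Boolean ``+``/``-``
notation is sugar for levels 1/0, handled at parse/serialization time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

__all__ = [
    "VariableSpec",
    "ConditionAtom",
    "Rule",
    "State",
    "ModelSpec",
    "Diagnostic",
    "ModelError",
    "validate_model",
]

#: Relational operators admitted in condition atoms.
OPS = (">=", ">", "<=", "<", "=")

_OP_EVAL = {
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
    "<=": lambda a, b: a <= b,
    "<": lambda a, b: a < b,
    "=": lambda a, b: a == b,
}


class ModelError(ValueError):
    """A model violates a structural invariant."""


@dataclass(frozen=True, order=True)
class VariableSpec:
    """A model variable with an ordered integer level domain ``0..kmax``.

    ``kmax == 1`` means the variable is Boolean (absent/present).
    """

    name: str
    kmax: int = 1

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise ModelError(f"invalid variable name {self.name!r}")
        if self.kmax < 1:
            raise ModelError(f"variable {self.name!r}: kmax must be >= 1, got {self.kmax}")

    @property
    def is_boolean(self) -> bool:
        return self.kmax == 1

    @property
    def levels(self) -> range:
        return range(self.kmax + 1)


@dataclass(frozen=True, order=True)
class ConditionAtom:
    """A threshold test ``variable op level`` (e.g. ``M >= 1``)."""

    variable: str
    op: str
    level: int

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise ModelError(f"unknown operator {self.op!r} in condition on {self.variable!r}")

    def holds(self, state: "State") -> bool:
        return _OP_EVAL[self.op](state[self.variable], self.level)


@dataclass(frozen=True, order=True)
class Rule:
    """A labeled event rule: condition atoms -> atomic level assignments.

    The condition is a conjunction; disjunctive causes are written as
    several rules sharing a realization.  The realization assigns target
    levels (absolute, not increments) to one or more variables at once.
    """

    label: str
    condition: tuple[ConditionAtom, ...]
    realization: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not self.label or any(c.isspace() for c in self.label):
            raise ModelError(f"invalid rule label {self.label!r}")
        if not self.condition:
            raise ModelError(f"rule {self.label}: empty condition")
        if not self.realization:
            raise ModelError(f"rule {self.label}: empty realization")
        seen: dict[str, int] = {}
        for var, lvl in self.realization:
            if var in seen and seen[var] != lvl:
                raise ModelError(
                    f"rule {self.label}: contradictory realization assigns "
                    f"{var}={seen[var]} and {var}={lvl}"
                )
            seen[var] = lvl
        # canonical ordering for stable hashing/printing
        object.__setattr__(self, "condition", tuple(sorted(set(self.condition))))
        object.__setattr__(self, "realization", tuple(sorted(seen.items())))

    def condition_holds(self, state: "State") -> bool:
        return all(atom.holds(state) for atom in self.condition)

    def assignments(self) -> Mapping[str, int]:
        return dict(self.realization)


@dataclass(frozen=True, order=True)
class State:
    """A total assignment of a level to every model variable.

    Stored canonically as a sorted tuple of ``(name, level)`` pairs, so
    states hash, compare and print stably.
    """

    assignment: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", tuple(sorted(self.assignment)))
        names = [n for n, _ in self.assignment]
        if len(names) != len(set(names)):
            raise ModelError(f"state assigns the same variable twice: {self.assignment}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "State":
        return cls(tuple(mapping.items()))

    def __getitem__(self, name: str) -> int:
        for n, lvl in self.assignment:
            if n == name:
                return lvl
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(n == name for n, _ in self.assignment)

    def as_dict(self) -> dict[str, int]:
        return dict(self.assignment)

    def apply(self, assignments: Mapping[str, int]) -> "State":
        """Return a new state with the given levels set, others unchanged."""
        new = dict(self.assignment)
        new.update(assignments)
        return State(tuple(new.items()))

    def render(self, model: "ModelSpec | None" = None, ascii_only: bool = False) -> str:
        """Human-readable state label.

        For all-Boolean models the label concatenates the names of present
        variables (``APT``); the empty community renders as ``∅`` (or ``-``
        in ASCII mode).  Otherwise ``name=level`` pairs are joined.
        """
        boolean = model.is_boolean if model is not None else all(
            lvl in (0, 1) for _, lvl in self.assignment
        )
        if boolean:
            present = "".join(n for n, lvl in self.assignment if lvl == 1)
            if present:
                return present
            return "-" if ascii_only else "∅"
        return ",".join(f"{n}={lvl}" for n, lvl in self.assignment)

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: which rule/variable, and what is wrong."""

    code: str
    message: str
    where: str = ""

    def __str__(self) -> str:
        loc = f" [{self.where}]" if self.where else ""
        return f"{self.code}: {self.message}{loc}"


@dataclass(frozen=True)
class ModelSpec:
    """A complete qualitative model: variables, rules and initial state(s).

    Construction only canonicalizes; call :func:`validate_model` (or
    :meth:`validated`) to check cross-referencing invariants, so that
    invalid models can still be inspected and diagnosed.
    """

    variables: tuple[VariableSpec, ...]
    rules: tuple[Rule, ...]
    initial_states: tuple[State, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "rules", tuple(self.rules))
        object.__setattr__(self, "initial_states", tuple(self.initial_states))

    def validated(self) -> "ModelSpec":
        """Return self if every invariant holds, else raise ModelError."""
        diags = validate_model(self)
        if diags:
            raise ModelError("; ".join(str(d) for d in diags))
        return self

    @property
    def variable_map(self) -> dict[str, VariableSpec]:
        return {v.name: v for v in self.variables}

    @property
    def is_boolean(self) -> bool:
        return all(v.is_boolean for v in self.variables)

    def rule(self, label: str) -> Rule:
        for r in self.rules:
            if r.label == label:
                return r
        raise KeyError(f"no rule labeled {label!r}")

    def state(self, **levels: int) -> State:
        """Build a valid state; unlisted variables default to level 0."""
        assign = {v.name: 0 for v in self.variables}
        for name, lvl in levels.items():
            if name not in assign:
                raise ModelError(f"unknown variable {name!r}")
            assign[name] = lvl
        s = State.from_mapping(assign)
        self.check_state(s)
        return s

    def check_state(self, s: State) -> None:
        """Raise unless ``s`` is a total in-domain assignment for this model."""
        vmap = self.variable_map
        names = {n for n, _ in s.assignment}
        if names != set(vmap):
            missing = sorted(set(vmap) - names)
            extra = sorted(names - set(vmap))
            raise ModelError(
                f"state is not total: missing {missing}, undeclared {extra}"
            )
        for n, lvl in s.assignment:
            if lvl not in vmap[n].levels:
                raise ModelError(f"state level {n}={lvl} outside domain 0..{vmap[n].kmax}")

    def all_states(self) -> Iterator[State]:
        """Enumerate the full state space (product of variable domains)."""
        import itertools

        names = [v.name for v in self.variables]
        for combo in itertools.product(*(v.levels for v in self.variables)):
            yield State(tuple(zip(names, combo)))


def validate_model(m: ModelSpec | object) -> list[Diagnostic]:
    """Check every structural invariant; return one diagnostic per violation.

    An empty list means the model is executable by the dynamics engine
    without runtime domain errors.  Never mutates the model.
    """
    diags: list[Diagnostic] = []
    variables: Iterable[VariableSpec] = getattr(m, "variables", ())
    rules: Iterable[Rule] = getattr(m, "rules", ())
    initial_states: Iterable[State] = getattr(m, "initial_states", ())

    vmap: dict[str, VariableSpec] = {}
    for v in variables:
        if v.name in vmap:
            diags.append(Diagnostic("duplicate-variable", f"variable {v.name!r} declared twice", v.name))
        vmap[v.name] = v

    seen_labels: set[str] = set()
    for r in rules:
        if r.label in seen_labels:
            diags.append(Diagnostic("duplicate-label", f"rule label {r.label!r} reused", r.label))
        seen_labels.add(r.label)
        for atom in r.condition:
            v = vmap.get(atom.variable)
            if v is None:
                diags.append(Diagnostic(
                    "undeclared-variable",
                    f"condition references undeclared variable {atom.variable!r}",
                    r.label,
                ))
                continue
            if atom.level not in v.levels:
                diags.append(Diagnostic(
                    "out-of-domain",
                    f"condition level {atom.variable}{atom.op}{atom.level} outside domain 0..{v.kmax}",
                    r.label,
                ))
            if v.is_boolean and atom.op != "=":
                diags.append(Diagnostic(
                    "boolean-operator",
                    f"Boolean variable {atom.variable!r} only admits presence tests "
                    f"(+/- or =0/=1), not {atom.op!r}",
                    r.label,
                ))
        for var, lvl in r.realization:
            v = vmap.get(var)
            if v is None:
                diags.append(Diagnostic(
                    "undeclared-variable",
                    f"realization assigns undeclared variable {var!r}",
                    r.label,
                ))
            elif lvl not in v.levels:
                diags.append(Diagnostic(
                    "out-of-domain",
                    f"realization {var}={lvl} outside domain 0..{v.kmax}",
                    r.label,
                ))

    inits = tuple(initial_states)
    if not inits:
        diags.append(Diagnostic("no-initial-state", "model declares no initial state"))
    for i, s in enumerate(inits):
        names = {n for n, _ in s.assignment}
        if names != set(vmap):
            diags.append(Diagnostic(
                "invalid-initial-state",
                f"initial state #{i} is not a total assignment over the declared variables",
                str(i),
            ))
            continue
        for n, lvl in s.assignment:
            if lvl not in vmap[n].levels:
                diags.append(Diagnostic(
                    "invalid-initial-state",
                    f"initial state #{i} sets {n}={lvl} outside domain 0..{vmap[n].kmax}",
                    str(i),
                ))
    return diags
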