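"""Plain-text model format: parser, serializer, JSON round-trip.

Grammar (UTF-8, line-oriented; ``#`` starts a comment, blank lines ignored)::

    variable <name> [levels 0..<k>]      # omitted levels => Boolean 0..1
    rule <LABEL>: <atom> [and <atom>]* >> <assign> [, <assign>]*
    initial: <assign> [, <assign>]*      # unlisted variables default to 0

    atom:   <name>+ | <name>- | <name> (>=|>|<=|<|=) <int>
    assign: <name>+ | <name>- | <name> = <int>

``v+``/``v-`` is sugar for ``v = 1``/``v = 0``.  The Unicode minus ``−``
and relation signs ``≥``/``≤`` are accepted as synonyms of ``-``, ``>=``
and ``<=``.  Parsing then serializing then parsing is the identity on
valid models.
"""

from __future__ import annotations

import json
import re

from .model import (
    ConditionAtom,
    ModelError,
    ModelSpec,
    Rule,
    State,
    VariableSpec,
    validate_model,
)

__all__ = ["ParseError", "parse_model", "serialize_model", "model_to_json", "model_from_json"]


class ParseError(ModelError):
    """Syntax or semantic error in a model file, with line/column."""

    def __init__(self, message: str, line: int, column: int = 1):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_VAR_RE = re.compile(rf"^variable\s+({_NAME})(?:\s+levels\s+0\.\.(\d+))?\s*$")
_RULE_RE = re.compile(rf"^rule\s+({_NAME})\s*:\s*(.+?)\s*>>\s*(.+?)\s*$")
_INIT_RE = re.compile(r"^initial\s*:\s*(.*?)\s*$")
_ATOM_RE = re.compile(rf"^({_NAME})\s*(>=|<=|>|<|=)\s*(-?\d+)$")
_SUGAR_RE = re.compile(rf"^({_NAME})\s*([+-])$")


def _normalize(text: str) -> str:
    return text.replace("−", "-").replace("≥", ">=").replace("≤", "<=")


def _parse_atom(tok: str, line: int, col: int, vmap: dict[str, VariableSpec]) -> ConditionAtom:
    tok = tok.strip()
    m = _SUGAR_RE.match(tok)
    if m:
        name, sign = m.groups()
        _check_declared(name, line, col, vmap)
        if not vmap[name].is_boolean:
            raise ParseError(
                f"'+/-' shorthand requires a Boolean variable, but {name!r} "
                f"has levels 0..{vmap[name].kmax}", line, col)
        return ConditionAtom(name, "=", 1 if sign == "+" else 0)
    m = _ATOM_RE.match(tok)
    if m:
        name, op, lvl = m.group(1), m.group(2), int(m.group(3))
        _check_declared(name, line, col, vmap)
        v = vmap[name]
        if v.is_boolean and op != "=":
            raise ParseError(
                f"Boolean variable {name!r} only admits '=' tests "
                f"(or the +/- shorthand), got {op!r}", line, col)
        if lvl not in v.levels:
            raise ParseError(f"level {lvl} outside domain 0..{v.kmax} of {name!r}", line, col)
        return ConditionAtom(name, op, lvl)
    raise ParseError(f"cannot parse condition atom {tok!r}", line, col)


def _parse_assign(tok: str, line: int, col: int, vmap: dict[str, VariableSpec]) -> tuple[str, int]:
    tok = tok.strip()
    m = _SUGAR_RE.match(tok)
    if m:
        name, sign = m.groups()
        _check_declared(name, line, col, vmap)
        if not vmap[name].is_boolean:
            raise ParseError(
                f"'+/-' shorthand requires a Boolean variable, but {name!r} "
                f"has levels 0..{vmap[name].kmax}", line, col)
        return name, 1 if sign == "+" else 0
    m = _ATOM_RE.match(tok)
    if m and m.group(2) == "=":
        name, lvl = m.group(1), int(m.group(3))
        _check_declared(name, line, col, vmap)
        if lvl not in vmap[name].levels:
            raise ParseError(f"level {lvl} outside domain 0..{vmap[name].kmax} of {name!r}", line, col)
        return name, lvl
    raise ParseError(f"cannot parse assignment {tok!r}", line, col)


def _check_declared(name: str, line: int, col: int, vmap: dict[str, VariableSpec]) -> None:
    if name not in vmap:
        raise ParseError(f"undeclared variable {name!r}", line, col)


def parse_model(text: str) -> ModelSpec:
    """Parse a model file into a validated :class:`ModelSpec`."""
    variables: list[VariableSpec] = []
    vmap: dict[str, VariableSpec] = {}
    rules: list[Rule] = []
    labels: set[str] = set()
    initial_states: list[State] = []

    for lineno, raw in enumerate(_normalize(text).splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        col = len(raw) - len(raw.lstrip()) + 1

        m = _VAR_RE.match(line)
        if m:
            name, kmax = m.group(1), int(m.group(2)) if m.group(2) else 1
            if name in vmap:
                raise ParseError(f"variable {name!r} declared twice", lineno, col)
            if kmax < 1:
                raise ParseError(f"variable {name!r}: levels upper bound must be >= 1", lineno, col)
            v = VariableSpec(name, kmax)
            variables.append(v)
            vmap[name] = v
            continue

        m = _RULE_RE.match(line)
        if m:
            label, cond_src, real_src = m.groups()
            if label in labels:
                raise ParseError(f"duplicate rule label {label!r}", lineno, col)
            labels.add(label)
            atoms = tuple(
                _parse_atom(tok, lineno, col, vmap)
                for tok in re.split(r"\s+and\s+", cond_src)
            )
            assigns: list[tuple[str, int]] = []
            seen: dict[str, int] = {}
            for tok in real_src.split(","):
                var, lvl = _parse_assign(tok, lineno, col, vmap)
                if var in seen and seen[var] != lvl:
                    raise ParseError(
                        f"rule {label}: contradictory realization assigns "
                        f"{var}={seen[var]} and {var}={lvl}", lineno, col)
                seen[var] = lvl
                assigns.append((var, lvl))
            rules.append(Rule(label, atoms, tuple(assigns)))
            continue

        m = _INIT_RE.match(line)
        if m:
            assign = {v.name: 0 for v in variables}
            src = m.group(1)
            if src:
                for tok in src.split(","):
                    var, lvl = _parse_assign(tok, lineno, col, vmap)
                    assign[var] = lvl
            initial_states.append(State.from_mapping(assign))
            continue

        raise ParseError(f"unrecognized line {line!r}", lineno, col)

    if not initial_states:
        raise ParseError("model declares no 'initial:' state", lineno if text.strip() else 1)

    spec = ModelSpec(tuple(variables), tuple(rules), tuple(initial_states))
    diags = validate_model(spec)
    if diags:
        raise ParseError("; ".join(str(d) for d in diags), 1)
    return spec


def _fmt_atom(atom: ConditionAtom, vmap: dict[str, VariableSpec]) -> str:
    if vmap[atom.variable].is_boolean and atom.op == "=":
        return f"{atom.variable}{'+' if atom.level == 1 else '-'}"
    return f"{atom.variable} {atom.op} {atom.level}"


def _fmt_assign(var: str, lvl: int, vmap: dict[str, VariableSpec]) -> str:
    if vmap[var].is_boolean:
        return f"{var}{'+' if lvl == 1 else '-'}"
    return f"{var} = {lvl}"


def serialize_model(m: ModelSpec) -> str:
    """Write a model back to the file format; re-parsing yields ``m``."""
    diags = validate_model(m)
    if diags:
        raise ModelError("cannot serialize invalid model: " + "; ".join(str(d) for d in diags))
    vmap = m.variable_map
    lines: list[str] = []
    for v in m.variables:
        lines.append(f"variable {v.name}" + ("" if v.is_boolean else f" levels 0..{v.kmax}"))
    if m.rules:
        lines.append("")
        for r in m.rules:
            cond = " and ".join(_fmt_atom(a, vmap) for a in r.condition)
            real = ", ".join(_fmt_assign(var, lvl, vmap) for var, lvl in r.realization)
            lines.append(f"rule {r.label}: {cond} >> {real}")
    lines.append("")
    for s in m.initial_states:
        nonzero = [(n, lvl) for n, lvl in s.assignment if lvl != 0]
        lines.append("initial: " + ", ".join(_fmt_assign(n, lvl, vmap) for n, lvl in nonzero))
    return "\n".join(lines) + "\n"


def model_to_json(m: ModelSpec) -> str:
    """Stable-key-order JSON serialization of a model."""
    obj = {
        "variables": [{"name": v.name, "kmax": v.kmax} for v in m.variables],
        "rules": [
            {
                "label": r.label,
                "condition": [
                    {"variable": a.variable, "op": a.op, "level": a.level}
                    for a in r.condition
                ],
                "realization": [{"variable": var, "level": lvl} for var, lvl in r.realization],
            }
            for r in m.rules
        ],
        "initial_states": [dict(s.assignment) for s in m.initial_states],
    }
    return json.dumps(obj, indent=2, sort_keys=False)


def model_from_json(text: str) -> ModelSpec:
    obj = json.loads(text)
    spec = ModelSpec(
        tuple(VariableSpec(v["name"], v["kmax"]) for v in obj["variables"]),
        tuple(
            Rule(
                r["label"],
                tuple(ConditionAtom(a["variable"], a["op"], a["level"]) for a in r["condition"]),
                tuple((a["variable"], a["level"]) for a in r["realization"]),
            )
            for r in obj["rules"]
        ),
        tuple(State.from_mapping(s) for s in obj["initial_states"]),
    )
    return spec.validated()
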