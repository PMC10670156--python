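# eden-qdm — qualitative discrete-event modeling of ecosystem dynamics

Ecosystems in data-poor settings resist quantitative modeling: rate
constants, interaction strengths and thresholds are costly to measure and
highly variable. This package implements a *qualitative, discrete-event,
possibilistic* alternative for ecologists and modelers: system variables
are abstracted to Boolean presence/absence (or a few ordered levels), and
change is expressed as labeled if-then rules

```
condition  >>  realization
```

where the condition is a conjunction of threshold atoms (`M+`, `M >= 1`)
and the realization atomically sets new levels (`S+`, `S2 = 0`). Rules
are executed *asynchronously* — one rule per step, though a single rule
may update several variables at once (partially synchronous scheduling) —
and *exhaustively*: every trajectory compatible with the rules is
computed, with no probabilities, priorities or durations. A synchronous
mode (all enabled rules at once) is provided for comparison.

The resulting **state-transition graph** (STG) is analyzed topologically:

- **stable states (deadlocks)** — states with no successor;
- **strongly connected components** — regions of mutually reachable
  states (*cyclic*: a single loop, the discrete analogue of a limit
  cycle; *complex*: interleaved feedback loops);
- **basins** — transient states grouped by the SCCs and stable states
  they lead to (*strong* when a single fate is certain);
- the **hierarchical transition graph** (HTG) — the acyclic condensation
  of the STG into these components, whose edges are the irreversible
  changes.

A model-checking layer answers the questions practitioners actually ask,
as named query patterns with witness trajectories: `reachable`,
`invariant`, `avoidable`, `stable`, and event necessity/sufficiency
(`precedes` / `suffices`).

## Worked example: community disassembly

Three protist species — *Amoeba proteus* (A), *Paramecium caudatum* (P),
*Tetrahymena pyriformis* (T) — interact: A eats and depends on P, A eats
T, and P outcompetes T. Each rule is an extinction event
(`examples/apt.eden`):

```
variable A
variable P
variable T

rule R1: A+ and P+ >> P-
rule R2: A+ and T+ >> T-
rule R3: P+ and T+ >> T-
rule R4: A+ and P- >> A-

initial: A+, P+, T+
```

```sh
$ eden analyze examples/apt.eden
update mode: asynchronous
states: 6  transitions: 6
deadlocks (stable states): 2: {∅}, {T}
transient states: 4
basin {A} (strong, fate determined): {A}, {AP} -> attractors ['{∅}']
basin {AT} (indeterminate fate): {AT}, {APT} -> attractors ['{T}', '{∅}']
maximal trajectories from initial state(s): 3
```

Starting from the full community {APT}, the possibilistic asynchronous
dynamics branch into **three alternative extinction sequences** —
{APT}→{AP}→{A}→{∅}, {APT}→{AT}→{A}→{∅}, {APT}→{AT}→{T} — ending in **two
stable communities**, {T} and the collapse {∅}. The four other states
are transient: {AP} and {A} are doomed to collapse (a strong basin),
while {APT} and {AT} still face either fate. Under synchronous
scheduling the same rules behave deterministically and only the collapse
survives:

```sh
$ eden analyze examples/apt.eden -m synchronous
update mode: synchronous
states: 3  transitions: 2
deadlocks (stable states): 1: {∅}
...
```

which is why the update mode is a modeling decision, not a detail: the
experimentally observed {T} endpoint exists only asynchronously.

The query layer recovers the historical explanation — P's extinction
(rule R1) is *necessary but not sufficient* for {T} to persist:

```sh
$ eden query examples/apt.eden --pattern precedes --predicate "T+ and A- and P-" --rule R1
verdict: True
$ eden query examples/apt.eden --pattern suffices --predicate "T+ and A- and P-" --rule R1
verdict: False
witness: {APT}→{AP}→{A}→{∅}
```

The counterexample fires R1 (at {AP}→{A}) yet still collapses.

Other subcommands: `eden run` (full report bundle with GraphML/DOT/TSV/
JSON exports), `eden fixtures <name>` (built-in models, including seeded
random ones), `eden validate`. The same functionality is available as a
library:

```python
from eden import apt_model, build_stg, classify_components, count_trajectories

g = build_stg(apt_model(), "asynchronous")
print(len(g.states), {g.render_state(s) for s in g.deadlocks})
# 6 {'T', '∅'}
print(count_trajectories(g)[0])
# 3
```

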