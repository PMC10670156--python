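# Methods

## Model semantics

A model is a finite set of variables, each with an ordered integer
domain `0..kmax` (`kmax = 1` for Boolean presence/absence), a set of
labeled rules, and one or more initial states. A rule

```
label: a1 and a2 and ... >> v1 = l1, v2 = l2, ...
```

has a *condition* — a conjunction of threshold atoms `v op l` with
`op ∈ {>=, >, <=, <, =}` — and a *realization* — an absolute assignment
of target levels to one or more variables, applied atomically. Boolean
`v+`/`v-` is sugar for `v = 1`/`v = 0`; internally everything is
integer-leveled, so there is a single code path. Disjunctive causes are
written as several rules sharing a realization; the rule label then
identifies *which* cause fired, which is what the event queries need.
For Boolean variables only equality tests are admitted (a `>=` on a
two-level domain invites reading quantitative meaning into a variable
that has none).

The interpretation of a rule is a *may*-transition: a satisfied
condition permits, never forces, the event. Exploration is therefore
**possibilistic** — the engine computes every trajectory compatible
with the rules, with no probabilities, rates, priorities or delays.
Abstracted quantitative detail (population sizes, interaction strengths,
hidden variables such as temperature) reappears only as nondeterminism.

### Enabledness is effect-bearing

A rule is enabled in state `s` iff its condition holds **and** its
realization changes `s`. A condition-only definition would put a
self-loop on almost every state, destroy the identification of
deadlocks with "no enabled rule", and add no information: qualitative
dynamics are about change. Consequence: transitions never have
`source = target`, and two rules writing opposite values to the same
Boolean variable can never be enabled simultaneously.

### Update modes

- **asynchronous** (default): exactly one enabled rule fires per
  transition. Since one rule may set several variables, this is the
  *partially synchronous* scheduling: events are serialized, but an
  event can be a joint change. With single-assignment rules it
  coincides with the fully asynchronous mode of Boolean networks.
- **synchronous**: all enabled rules fire at once; the dynamics are
  deterministic (out-degree ≤ 1). If two enabled rules assign different
  levels to one variable, the default is a hard
  `SynchronousConflictError` naming both rules and the variable —
  simultaneous contradictory events have no natural semantics, and a
  silent resolution would hide a modeling error. An opt-in extension
  (`branch_on_conflict`) instead branches over all maximal
  conflict-free subsets of the enabled rules.

Edges merge alternative causes: the transition `{APT}→{AP}` carries
`{R2, R3}` because predation and competition each suffice to remove T.
Merging (rather than multi-edges) keeps the graph a simple digraph and
matches how the trajectory count is read off the state paths.

### Graph construction

`build_stg` runs a breadth-first closure of the successor relation from
the initial states: exactly the reachable states, with maximal label
sets per edge. States are expanded in canonical sorted order and rules
tried in label order, so rebuilding the graph — and every export — is
byte-identical across runs. Exceeding `max_states` (default 1,000,000;
qualitative state spaces grow exponentially in the number of variables)
aborts with an explicit error rather than returning a truncated graph.

## Topology

- **deadlock / stable state**: a state with no successor.
- **SCC**: maximal set of mutually reachable states (computed via
  networkx' Tarjan-style algorithm; an independent pairwise-reachability
  oracle checks it in the tests). Non-trivial SCCs are **cyclic** iff
  every member has internal in- and out-degree 1, else **complex**.
- **basin**: transient states (outside all non-trivial SCCs and
  deadlocks) grouped by the set of components they lead to. "Not part
  of an SCC" is read as *non-trivial* SCC — every state is trivially its
  own SCC, so the literal reading would leave basins empty.

Basin grouping keys on the set of **all** reachable non-trivial SCCs
and deadlocks. The exposed `attractor_key` is the terminal part of that
key — the deadlocks and inescapable SCCs that are the basin's possible
fates; a singleton key marks a **strong** basin (fate determined).
Keying on terminal components alone looks equivalent but is not: a
basin upstream of an *escapable* SCC can share its terminal fates with
a basin downstream of it, and merging them would put a
`basin → SCC → basin` cycle in the condensation. Including the
reachable SCCs in the grouping key separates those states (an edge
leaving an SCC can never re-enter it, by maximality), which makes the
**hierarchical transition graph** — components as nodes, an edge where
at least one state transition crosses between two components — acyclic
by construction; `build_htg` still asserts acyclicity on every build as
a defense against regressions. Non-terminal SCCs stay their own HTG
nodes: they are qualitatively different objects (reversible regions)
from basins, and the crossing rule handles their edges uniformly.

**Trajectories.** For an acyclic STG, the trajectories are the maximal
simple state paths from the initial states — for the disassembly
example, the three extinction sequences. Under cycles "a trajectory"
is ill-defined at state level (infinitely many unwindings), so the
count moves to the HTG, which is finite and acyclic; each HTG step
carries the union of the crossing labels. Enumeration is capped
(default 100,000) with an explicit error, as path counts can be
exponential in graph size.

## Queries

Six fixed patterns, not a temporal-logic parser — the formalism the
patterns abbreviate is a known adoption barrier outside formal methods:

| pattern | verdict true iff |
|---|---|
| `reachable(p)` | some reachable state satisfies `p` |
| `invariantly(p)` | every reachable state satisfies `p` |
| `avoidable(p)` | some maximal trajectory never enters `p` |
| `stable_in(p)` | some terminal component lies entirely within `p` |
| `event_precedes(r, p)` (necessity) | every path from an initial state into `p` crosses an edge labeled `r` |
| `event_suffices(r, p)` (sufficiency) | every maximal trajectory firing `r` visits `p` |

Necessity is evaluated from the initial states only (a historical
explanation of how `p` can come about, not a global property of all
states). "Maximal trajectory" imposes **no fairness**: a trajectory may
enter a cycle and stay there forever, so avoidability and sufficiency
counterexamples may be lasso-shaped; the witness then shows the cycle
once. Necessity counts an edge as an `r`-event when `r` is *in* its
merged label set — on a merged edge the alternative cause may be the
one that fired, which is the honest possibilistic reading. All verdicts
come with witness paths re-validated against the graph; ties are broken
shortest-first, then by canonical state order, so query output is
deterministic.

## Fixtures and the synthetic-model generator

The built-in models regenerate the documented study systems: the
three-species disassembly model (three Boolean variables, four
extinction rules, initial `{APT}`), the Boolean and multivalued
seed-germination models (one vs. three moisture thresholds), plus two
minimal topology probes (`toggle`: one complex SCC; `cycle3`: one
cyclic SCC). The disassembly rule set is the minimal
conjunction-of-presence reconstruction of the described interactions —
one extinction rule per interaction plus the dependence rule — and is
accepted because it reproduces every documented behavior *jointly*
(see `tests/test_fixtures.py`).

`random_model(n_vars, n_rules, seed)` generates seeded Boolean models
(1–3 condition atoms, 1–2 assignments per rule, uniform levels) as
property-test drivers. These are structural stress tests, not
ecologies: they have no interaction-graph realism, no multivalued
variables (multivalued paths are exercised by the germination and
staircase fixtures), and their state spaces are capped at 2^8 by
construction in the tests. Passing them shows the engine's transition
relation, SCC/basin classification and HTG construction are correct on
arbitrary rule structures — it says nothing about the ecological
adequacy of any particular model.

Test and acceptance problem sizes — ≤ 8 variables, 200 random models,
50 HTG checks — keep the whole verification exhaustive (brute force
over the full product state space is the oracle) while finishing in
seconds; they are sizes at which exhaustive ground truth is computable,
not a limit of the engine.

## Numerical / procedural choices

- Canonical state form: variables in sorted name order; Boolean model
  states render as present-variable strings (`APT`, `∅`; `-` in ASCII
  mode), multivalued as `name=level` lists.
- All set-valued outputs (components, edges, witnesses, exports) are
  sorted; reports are diffable and reruns byte-identical.
- Degenerate inputs: a model with no rules yields a one-state STG whose
  single state is simultaneously deadlock and sole trajectory; an
  unsatisfiable predicate is trivially avoidable and never reachable;
  an initial state already satisfying `p` makes `reachable(p)` true
  with an empty witness and necessity false (the empty path fires no
  rule).
- Seeds: every stochastic element (random-model generation) flows from
  an explicit integer seed; there is no hidden global randomness.

## Known limitations

- No probabilistic, timed or prioritized semantics — deliberately out
  of scope of the possibilistic framework.
- Explicit-state representation only: state spaces beyond `max_states`
  abort rather than switching to symbolic (decision-diagram) encodings.
- The query layer is the six patterns above, not full CTL/LTL.
- Synchronous conflict branching (the maximal-subset extension)
  enumerates subsets of the enabled rules; it is exponential in the
  number of *conflicting* rules and intended for small models.
- Spatial structure, continuous abstraction refinement and
  counterfactual causality analysis are not implemented.
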