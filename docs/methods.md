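# Methods

## Model representation

A Boolean network is an ordered list of named variables, one rule per
variable, built from constants, variables, `!`, `&`, `|`. Rules are immutable
syntax trees; structural equality is used for round-trip guarantees
(`parse ∘ serialize = id` on `.bnet` text). Node names are restricted to
`[A-Za-z0-9_]+`; complex-species names (e.g. `IKBA/NFKB/RELA`) are normalised
to underscores at parse time.

**Input convention.** A node is an *input* iff its rule is exactly its own
variable or a constant. This matches the idiom of models inferred from
molecular interaction maps, where inputs are emitted as self-loops; it makes
input detection deterministic, and it means inputs are inert under every
dynamics in the package (their rule always agrees with their value), so
setting an input's initial value and clamping it are equivalent.

**SBML-qual.** Only strictly Boolean documents are accepted (maxLevel ≤ 1,
MathML restricted to and/or/not and eq-against-0/1; a bare `ci` means
"species is 1"). Function terms are assumed non-overlapping, as produced by
the common exporters: the rule is the disjunction of the level-1 terms, or,
when the default level is 1, additionally the negation of the level-0 terms.
Anything outside the dialect raises an error naming the offending element;
nothing is silently dropped. Multi-valued logic is out of scope.

## Value propagation

Seeds (clamped inputs or mutated internal nodes) are substituted into all
remaining rules; a rule that becomes constant fixes its node and the constant
propagates, iterating to a fixpoint (deterministic declaration-order
worklist; the result is confluent, which the tests check by permuting
declaration order). Seeding an internal node *clamps* it — its own rule is
discarded — which is the same semantics as a knock-out/knock-in mutation, so
drugs, mutations and input assignments all reduce to one mechanism.

Constancy detection goes beyond constant folding: after substitution a rule
with ≤ 12 support variables is checked for constancy by exhaustive
enumeration (supports in curated signalling models are far smaller). This is
sound for trap-space preservation: if a rule is tautologically b, every
terminal trap space must fix its node at b, because fixing it yields a
strictly smaller trap space.

The reduced model preserves all terminal trap spaces of the clamped original;
this is asserted wholesale in the test suite against the brute-force oracle
on 200 random networks.

## Terminal trap spaces

A subspace (per-node value in {0, 1, −1}, −1 = free) is a trap space when
every fixed node's rule evaluates to the fixed value under every completion
of the free variables (checked exhaustively over the rule's support —
"standard" trap-space semantics; most-permissive semantics is not
implemented). Terminal = inclusion-minimal.

Identification is exact and deliberately desk-scale rather than symbolic:

1. percolate constant rules (empty-seed propagation);
2. if more than `free_limit` (default 20) nodes remain free, raise a capacity
   error advising input fixing first;
3. on the free core, enumerate asynchronous attractors as bottom SCCs of the
   explicit state-transition graph;
4. take the percolation-closure of each attractor's span (free any fixed node
   whose rule can deviate within the subspace, to stability);
5. filter to inclusion-minimal subspaces and re-attach the percolated
   constants.

Correctness rests on the fact that every minimal trap space contains an
attractor and equals the closure of that attractor's span; the package also
ships a 3ⁿ brute-force enumerator (≤ 8 nodes, extendable for testing) used as
an independent oracle, and the two routes are required to agree exactly on
hundreds of seeded random networks. The cost of the STG step is O(2ᶠ) in the
free-core size — in practice scenarios clamp all inputs and leave a handful
of free nodes (four in the fixture's inflamed condition). Computing trap
spaces of a 300-node model without fixing inputs is explicitly out of scope.

## Asynchronous dynamics

Attractors: bottom SCCs of the asynchronous STG (capacity 18 nodes); a
singleton bottom SCC has no unstable variable and is a fixed point. Random
walks flip one uniformly chosen unstable node per step (state repeats when
none is unstable); the RNG seed is a required parameter and traces are
reproducible bit-for-bit. Oscillation statistics are computed on the
post-burn-in segment (default burn-in 10% of the trace): a node is
*oscillating* when it toggles ≥ 2 times with activity fraction strictly
between 0 and 1, otherwise stably-ON/OFF by its final value. The ≥ 2-toggle
threshold separates genuine recurrence from a single settling transition.

## Continuous-time stochastic simulation

Exact Gillespie simulation of the continuous-time Markov jump process whose
events are asynchronous flips: eligible events in a state are the flips of
non-clamped nodes whose rule disagrees with their value; node v rises with
propensity `rate_up[v]` and falls with `rate_down[v]` (defaults 1.0 —
neutral kinetics, since only qualitative endpoint classifications are
interpreted); waiting times are exponential in the propensity sum and the
flip is chosen proportionally. A state with no eligible flip is absorbing.
Oscillating systems simply yield intermediate probabilities (the fixture's
TP53 motif hovers near 0.5), never errors.

Ensembles report per-node activation probabilities on a uniform 200-point
grid over [0, max_time]; `max_time` defaults to 40, by which every
non-oscillating cascade in the fixture has long converged. Curve lookups are
last-observation (step) interpolation, so a Monte-Carlo estimate refers to
the grid time at or before the query time — comparisons against closed forms
in the tests evaluate the law at that grid time, leaving pure binomial error
(standard error √(p(1−p)/n)). Initial conditions are per-node Bernoulli
probabilities (default 0) plus clamped nodes excluded from flipping;
unlisted inputs in a scenario are clamped to 0, the quiescent baseline,
unless the condition is explicitly all-active. Determinism: one seeded
generator drives the whole ensemble; identical seeds give identical output
arrays.

## Scenarios and screening

Every condition runs the same pipeline: clamp mutations → assign listed
inputs, remaining inputs to the scenario default → propagate → terminal trap
spaces → phenotype readout. A phenotype is 0/1 only when *all* terminal trap
spaces agree on that fixed value; it is −1 (undefined) when unfixed or when
trap spaces disagree — a single condition is reported as a single
ON/OFF/unfixed value. Scores: 1 when expected and obtained are both defined
and equal, 0 when both defined and different, −1 when either is undefined.

Drugs are clamp sets (inhibitor → 0, activator → 1); multi-target drugs clamp
all targets, combinations are unions. Targets absent from the model are
recorded and skipped with a warning so published drug tables can be applied
to reduced models unchanged. The combination search is breadth-first over
clamp subsets by increasing size in the candidate-list order, pruning
supersets of found solutions; results are therefore inclusion-minimal and
deterministic. Whether targets are clamped before or after input assignment
is irrelevant under clamping semantics.

## The fixture model

The packaged 53-node network (17 inputs, 31 intermediates, 5 phenotype
sinks) is a constructed desk-scale emulation, not the deposited large-scale
model: it encodes the printed apoptosis rules verbatim and reproduces the
qualitative input–output behaviours of the full model, but none of its
counts (component totals, module sizes) transfer. Two choices were genuinely
open and are fixture design decisions:

- **NFKB → endogenous IL-6 routing.** The model must satisfy both "TNF/IL-17
  activate inflammation only with the IKBA/NFKB/RELA complex" and "blocking
  the IL-6 axis alone silences inflammation under all-active inputs". Routing
  NFKB activity through endogenous IL-6 production into the shared IL-6
  receptor signal satisfies both and mirrors the documented NF-κB→IL-6 axis.
- **MMP3 gating of MMP1/MMP9.** MMP1 and MMP9 require both their pro-enzyme
  input and MMP3, so MMP3 knockout alone abolishes matrix degradation while
  MMP1-specific conditions still work (pro-MMP activation).

Also deliberate: the proliferation rule makes CREB1 and YWHAQ each
individually necessary, so targeting either alone suppresses the phenotype
(the weaker reading — only the pair suffices — was rejected as it would make
the published single-target observation unreproducible); and several
drug-table targets (IL1B, CD28, TLR4, Calcineurin, RAC1) are intentionally
absent from the fixture to exercise the skip-with-warning path.

What passing the suite shows — and does not. The generator emulates the
*logic-level* phenomena: signal sufficiency/necessity, dominant-negative
regulation, negative-feedback oscillation, knockout phenotypes. It does not
emulate the scale, redundancy or parameter uncertainty of the real 300-node
model, so passing tests demonstrate the correctness of the pipeline and the
reproducibility of the qualitative behaviours, not quantitative properties
of the arthritic joint.

## Problem sizes and numerical choices

Property suites use 200 seeded random networks (≤ 8 nodes for oracle
equality, ≤ 10 for preservation) — sizes at which the 3ⁿ oracle is exact and
fast. Stochastic checks use 10 000 trajectories for the closed-form law
(3σ binomial tolerance) and 5000 for endpoint classifications (thresholds
0.95/0.05 at t = 40); random walks use 5000 steps with a fixed seed. Ties
and degenerate inputs: empty conjunction/disjunction constructors collapse
to the neutral constant; double mutation of a node keeps the last clamp;
subspace orderings and search orders are lexicographic in declaration order
so that all outputs are reproducible.

## Known limitations

- No symbolic (BDD/ASP) trap-space computation: models must be reduced by
  input fixing to ≤ 20 free nodes.
- Synchronous-update attractor search is not implemented (defined in the
  field but unused in this pipeline).
- SBML-qual support is read-only and Boolean-only.
- Transition rates are not inferred from data; stochastic results are
  interpreted qualitatively (endpoint classification), not as calibrated
  kinetics.
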