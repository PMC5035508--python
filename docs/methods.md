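# Methods

## Model class and scope

`bncontrol` analyzes *synchronous, deterministic* Boolean networks: all n
nodes update simultaneously under `x(t+1) = F(x(t))`. Steady states do not
depend on the update order, so the steady-state-creation and region-blocking
results transfer to asynchronous interpretations of the same rules;
transition blocking and all basin statements are specific to the synchronous
scheme. Asynchronous/stochastic semantics, multistate variables and
network reduction are out of scope.

## Polynomial representation

Every update rule is stored in algebraic normal form (ANF): a set of
multilinear monomials over GF(2), with `a ∧ b = ab`, `a ∨ b = a+b+ab`,
`¬a = 1+a`. ANF is canonical — two rules denote the same Boolean function
iff their term sets are equal — which has two load-bearing consequences:

* the wiring diagram is syntactic *and* semantic: `x_j → x_i` is an edge
  exactly when `x_j` occurs in the ANF of `f_i`, which is exactly
  functional dependence (no cancellation artifacts can survive
  canonicalization);
* equality tests on controlled/specialized networks are exact term-set
  comparisons.

Bitstrings are written with `x_1` leftmost everywhere (files, CLI, JSON).

## Gröbner bases in the Boolean quotient ring

All ideal computations run directly in `F₂[x₁..x_n]/(x_i²+x_i)`: products
are reduced multilinearly at construction, so the field equations never
appear as explicit generators. The Buchberger loop processes, besides the
usual S-pairs (squarefree lcm), one extra task per basis element f and per
variable x dividing its leading monomial: the multilinear normal form of
S(f, x²+x), which is the idempotent product x·f. These tasks are what make
quotient-ring Buchberger complete — e.g. `⟨xy+x+y⟩` must yield `⟨x, y⟩`,
which pairwise S-polynomials alone never find. Pairs whose leading
monomials are coprime to a field equation's (`x ∤ lm(f)`) reduce to zero
immediately and are skipped. After saturation the basis is minimalized and
tail-interreduced, giving the unique reduced basis for the order.

Orders: graded-reverse-lex by default; pure lex over the ranking
“eliminated block first, then kept block, each in declared order” for
elimination. In the quotient ring every ideal is the vanishing ideal of its
{0,1} variety, so correctness is additionally pinned down in the tests by
exhaustive solution-set comparison and by a sympy cross-check (Gröbner
basis over GF(2) with field equations appended; every member of our basis
must reduce to zero against it).

## Solving and counting

`solve_system`/`count_solutions` first split the generators into connected
components by shared variables. Components with ≤ 22 variables are
enumerated exhaustively (bit-parallel numpy evaluation over all
assignments, ~4M max); larger components fall back to a variable-splitting
search with constant propagation. Counts multiply across components, with
a factor 2 per unconstrained variable. The decomposition is what makes
per-node control systems cheap: each control variable occurs only in the
update it modifies, so the blocks are small regardless of network size.
Both solver paths are tested for agreement.

## Control encodings and policies

Edge deletion substitutes `x_i ↦ (u_{i,j}+1)·x_i` inside `f_j` only; node
control wraps the node's own update as `(u⁻+u⁺+1)·f + u⁺`. Setting all
controls to zero reproduces the base network exactly, and each control
variable is local to its target update (both properties are asserted in
tests). The negation setting `u⁻ = u⁺ = 1` is representable but filtered
from enumerated policies by default (`exclude_negation=False` re-enables
it): flipping a rule's output is rarely a realizable intervention.

Solutions are reported at two granularities. `raw` is the set of *total*
assignments of the active controls solving the equations (with its exact
cardinality `raw_count`, computed even when the set itself is too large to
materialize); `minimal` is the set of support-minimal policies — active
sets no proper subset of which already solves the problem, free controls
at 0 — which is how intervention lists are usually read. For
steady-state creation, `occurring_count` additionally counts assignments
over only the control variables that actually occur in the reduced system,
the natural count when the remaining controls are irrelevant.

## The three tasks

* **create_steady_state** solves `F_j(y₀,u) + y₀ⱼ = 0`. Minimal supports
  are assembled as cartesian products of per-component minimal supports
  (valid because components constrain disjoint controls).
* **block_transition** keeps the product `∏(F_j(x₀,u)+z₀ⱼ+1)` factored:
  the factors have pairwise-disjoint control variables, so the non-blocking
  count is a product of per-factor counts and minimal blockers are the
  union of per-factor minimal solutions, filtered for global minimality.
  Expanding the product (worst case exponentially many terms) is never
  needed.
* **block_region** builds the steady-state system joined with the region
  clamps over state *and* control variables. For small joint spaces (≤ 20
  variables) it eliminates the state block and returns the controls
  outside the projection — raw set and exact minimal set included. For
  larger spaces (e.g. 16 nodes with 32 node controls, where the raw
  complement has ~2³² elements) it switches to an exact candidate search:
  supports of size 0..`max_support` (default 3) are tested directly, a
  candidate blocking iff the specialized network has no fixed point in the
  region (checked by bit-parallel enumeration of the region's states).
  Supersets of found blockers are skipped, which is sound for minimality
  because all smaller supports have already been tested. The support-size
  cap is the one deliberate incompleteness: minimal policies larger than
  the cap would be missed (none exist at depth 3 for the bundled models).

Conceptual/readout nodes (e.g. a phenotype flag like Apoptosis) can be
excluded from intervention via `exclude_controls`; nothing is excluded by
default, so a trivially blocking "force the readout" policy will be
reported unless the caller opts out.

## Dynamics

The transition map is materialized for n ≤ 22 (hard refusal above — no
silent sampling) by evaluating each ANF update over all 2^n states at once
with boolean numpy arrays. Attractors come from pointer-doubling on the
successor array (n squarings reach F^(2^n), which lands every state on its
terminal cycle), cycles are unwound by following successors, and basins are
bincounts of terminal labels. Basin sizes include the attractor's own
states; percentages are reported to two decimals of 2^n. Attractor cycles
are stored starting from their lexicographically smallest state;
policy rankings sort by descending basin with lexicographic tie-break on
support, so all outputs are byte-stable.

`prune_nonessential` drops an active edge control when, with the *other*
active controls applied, the target update no longer depends on the edge's
source (the deletion is then vacuous); pruning repeats to a fixed point and
asserts that the specialized updates are unchanged.

## Random-network generator

Property tests draw networks with n nodes and in-degree ≤ k: each node
receives a uniformly random truth table over a uniformly random input set
of size 0..k, converted to ANF by the binary Möbius transform, fully
determined by an integer seed. This emulates the sparse regulation of
biological networks (few inputs per gene) but none of their structural
biases (no canalization, no degree heterogeneity, no signed-monotone
rules); passing property tests therefore certifies the *algebra* — ANF
canonicity, Gröbner solution preservation, encoding identities, basin
partitions — on arbitrary sparse rules, not any biological realism of the
instances. Defaults in the tests (n ≈ 5–8, k ≈ 2–3, tens of draws) keep
exhaustive oracles — truth tables, 2^n state sweeps, subset checks —
exact, which is the point of the scale choice: every random instance is
small enough to verify against brute force.

## Numerical and degenerate-input conventions

* Empty term set = the zero polynomial; the empty monomial = 1; the unit
  ideal's reduced basis is `{1}` and is never simplified away.
* Enumeration thresholds: 22 variables per solver component and 22 network
  nodes; both are arguments, not environment-dependent.
* Edge control of a non-edge is an error (it would silently do nothing);
  duplicate controls are errors; specializing an unknown control is an
  error; `basin_of_state` of a non-fixed state is an error.
* Ties everywhere break lexicographically (variable order: declared space
  order; policies: support size, then sorted names).

## Known limitations

* Exhaustive dynamics caps at 22 nodes; there is no sampling estimator.
* `block_region`'s search path bounds minimal-policy size by
  `max_support`; raw blocking counts are not reported in that regime.
* Transition blocking assumes each product factor's controls are disjoint,
  which holds for the built-in encodings but would not for a hand-built
  controlled network whose control variables span multiple updates (a
  `NotImplementedError` guards this).
* Only synchronous update; limit cycles and basins under other schedules
  differ.
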