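# Methods

## Model and steady-state semantics

A Boolean network is a directed graph whose non-input nodes carry update
rules built from k-ary AND/OR, NOT and pass-through gates; inputs are source
nodes holding a default value (1, "available", unless declared otherwise —
the convention under which source compounds of the bundled metabolic-style
case study are active).  An intervention is a support set `S` of nodes
clamped to enforced values `z`, overriding their logic.

The MILP encodes *steady states of the intervened network*: gate constraints
compute each node's logic value `x̂_i` from its parents' **final** values
`x_i`, and the four-inequality linearization of
`x_i = (1−u_i)·x̂_i + u_i·z_i` switches each node between "follows its rule"
and "clamped to z".  For a fixed `(u, z)` the feasible `x` vectors are
therefore exactly the fixed points of the clamped network (verified
exhaustively in the test suite, including cyclic wiring).  Two consequences
are worth stating plainly:

* On **acyclic** networks the clamped fixed point is unique, so the MILP,
  synchronous simulation and the brute-force oracle all agree by
  construction.
* On **cyclic, multistable** networks the solver may select *any* consistent
  fixed point.  This is permissive: a solution means "a steady state with
  the desired target value exists", not "every trajectory reaches it".
  Fixed points are exactly the states stable under both synchronous and
  asynchronous update, so the prediction is update-scheme-independent, but
  basins of attraction are out of scope.

## The selective problem

The two networks share one perturbation-flag vector `u` and (by default,
`tie_z = True`) one enforced value per shared perturbed node: an intervention
is one physical action applied identically to both circuits.  Each network
then relaxes to its own fixed point, and the target constraints demand
opposite values.  The objective `min Σ u_i` counts perturbed nodes.

A stricter reading — forcing every *unperturbed* shared node to carry equal
final values in both networks (`x_i^A − x_i^B ≤ u_i` and symmetrically) — is
implemented as `ProblemSpec(couple_states=True)` but is **off by default**,
as a deliberate design choice: a single clamped node generally propagates
differently through differently wired networks, so demanding state equality
downstream either forces `u = 1` (and objective weight) on every diverging
node or, with tied enforced values, yields outright infeasibility.  On the
bundled case study the default semantics produce the three documented
single-node interventions; the strict coupling admits no solution at all.
The strict primitive remains available (and unit-tested) for users who want
"no off-target state changes" as a hard constraint with untied `z`.

When the target is missing from one network, that network simply receives no
target constraint; nodes unique to one network get a `u` flag but no
cross-network tie.

## Enumeration, ranking, minimality

All optimal supports are collected by repeated solves with support-based
no-good cuts (`Σ_{i∈S} u_i − Σ_{i∉S} u_i ≤ |S|−1`), which exclude exactly the
incumbent support while keeping supersets feasible; enumeration stops when
the objective rises past the optimum (or a caller-supplied bound, for ranked
pools feeding the subset-scan workflow: sort network-A solutions by
objective, return the first contained in a network-B solution).  Solutions
differing only in `z` over the same support are collapsed to one record —
supports, not variable assignments, are the scientific object.  The pool
limit defaults to 10,000.

A support is certified minimal by removal re-solves: keep `u_i = 1` on the
surviving elements, clamp `u_i = 0` *everywhere else* (without this clamp the
solver could substitute fresh nodes and nothing would ever certify), and
check that dropping any one element (or up to `depth` elements) is
infeasible.  Global optima pass this necessarily; the test matters for
ranked/suboptimal candidates.

## Elementary-mode validation

Two EM notions coexist deliberately:

* **Stoichiometric**: a support-minimal nonzero flux with `N v = 0` on
  balanced species and `v ≥ 0` (reversible reactions split into forward /
  `__rev` halves first; futile two-cycles of a split pair are pruned, not
  reported).  Feasibility of a candidate support is a pure LP; minimality is
  the MILP `min Σ y_j` with big-M linking `0 ≤ v_j ≤ M y_j` and total-flux
  floor `Σ v_j ≥ ε_tot`, minimal iff the optimum equals `|S|`.  Defaults
  `M = 1000`, `ε_tot = 1e-3` (dimensionless rates): `M` must exceed any
  attainable flux and `ε_tot` must be distinguishable from zero at solver
  tolerance; both are overridable per call.  Flux witnesses satisfy balance
  to 1e-9.
* **Boolean activation routes**: support-minimal node sets whose exclusive
  activation (set members 1, everything else 0) is a fixed point containing
  the target.  Case-study networks encode compounds *and* reactions as plain
  Boolean nodes, so this is the notion their route decompositions use.

The selectivity check prefers interventions whose support is a mode of
network A and **not** of network B (membership by set equality on supports;
the empty set is never a mode).  Failing the check only flags a solution
(`em_status = "other"`), it never deletes one.

The brute-force EM enumerator scans supports by increasing size with
superset pruning and is guarded to 15 reactions; it is an oracle for tests
and validation, not a scalable algorithm — at scale EM enumeration is
exactly the combinatorial explosion the MILP-first workflow avoids.

## Solver

HiGHS via `scipy.optimize.milp`/`linprog`, integer tolerance 1e-6, MIP gap 0.
Single-threaded HiGHS is deterministic for a fixed model and enumeration
output is sorted, so results are reproducible byte-for-byte; the configured
seed is recorded in logs for provenance.  Infeasibility and proven optimality
are distinguished from time-limited runs, which surface explicitly.

## Case-study reconstruction

The bundled 13-node two-network pair is a reconstruction from its published
description, shipped as data (rule files) so an alternative topology can be
substituted without code changes.  The published account of the structural
delta is internally inconsistent (a figure caption names a `c5 → c9` edge
difference, the body text names only the `r3 → C2` linkage); the committed
rules follow the body text plus the `C2 → C4` dependency implied by the
described inhibition cascade — the minimal rule set that simultaneously
reproduces, by computation, the three printed network-B routes, the single
network-A route, and the printed optimal intervention family
`{{C6},{C7},{r3}}`.  One described effect ("inhibition of C2 … inhibits C6")
cannot hold in any reconstruction where C6 is a source input and is treated
as unreproducible.

## Synthetic generators and what passing tests show

`random_pair` draws acyclic networks (nodes topologically ordered at
generation; 1–3 parents per regulated node, AND/OR gates, 25% negated
literals) and derives network B by a fixed number of single-edge additions or
removals — the "structurally similar pair" regime of the method, sized (≤ 10
nodes in tests) so the brute-force oracle over all
`(support, enforced-value)` interventions is exhaustive.  `random_stoich`
draws 8-reaction mostly-forward conversion networks with occasional backward
edges and two-substrate reactions between six species, two of them boundary.
Oracle-equivalence passes on these demonstrate *encoding correctness* under
fixed-point semantics; they do not establish anything about real regulatory
networks' size, logic depth, feedback density, or the biological fidelity of
any particular Boolean abstraction.  Problem sizes in tests and in
`scripts/acceptance.py` (200 and 60 pairs, 50 and 12 random models) were
chosen to keep exhaustive oracles exact while sampling all generator regimes.

## Known limitations

* No weighted objectives (druggability/essentiality priors); per-node
  objective coefficients are the natural hook.
* Single target node; multi-target trade-offs are not modeled.
* No attractor analysis beyond fixed points; no asynchronous or
  probabilistic semantics.
* SBML-qual import is not provided; the rule-file dialect and JSON exchange
  format are the interfaces.
* Enforced values `z` are reported verbatim per solution; no
  activation/repression reporting convention is imposed.
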