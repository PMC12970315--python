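# selnet

Minimal **sel**ective interventions in Boolean regulatory **net**works via
mixed-integer linear programming.

## The problem

Pathological cells (tumour subclones, epileptic microcircuits, unwanted
microbial strains) often run *almost* the same regulatory circuitry as their
healthy counterparts, differing only by a few rewired edges.  A therapeutic
intervention should exploit exactly those differences: force a target node
**off** in the pathological network while leaving it **on** in the healthy one
(or vice versa), by clamping as few nodes as possible.

`selnet` models each network as a Boolean network `G(V, F)` with synchronous
update `x_i(t+1) = f_i(x_{i1}(t), …, x_{ik}(t))` and finds minimum-size
intervention sets `S` with enforced values `z` such that the intervened
networks reach steady states with opposite target values
`x*_A = d_A ≠ d_B = x*_B`.

## The method

Each node *i* of each network contributes four binary decision variables —
final value `x_i`, logic value `x̂_i`, perturbation flag `u_i` (shared across
networks) and enforced value `z_i` — tied together by the exact linearization
of `x_i = (1−u_i)·x̂_i + u_i·z_i`:

```
x_i − x̂_i ≤ u_i        x_i − z_i ≤ 1 − u_i
x̂_i − x_i ≤ u_i        z_i − x_i ≤ 1 − u_i
```

Boolean rules are decomposed into gates and linearized exactly
(`AND: w ≤ a_j, w ≥ Σ a_j − (k−1)`; `OR: w ≥ a_j, w ≤ Σ a_j`; `NOT: w = 1−a`),
with gate inputs reading the parents' *final* values, so the feasible `x`
vectors are precisely the fixed points of the clamped network.  The objective
`min Σ u_i` minimizes the number of perturbed nodes; target constraints pin
`x*` per network.  Alternative optima are enumerated with support-based
no-good cuts `Σ_{i∈S} u_i − Σ_{i∉S} u_i ≤ |S|−1`, each support is certified
minimal by single-element-removal re-solves, and candidates can be validated
post hoc against **elementary modes**: support-minimal steady fluxes
`N v = 0, v ≥ 0` of a stoichiometric model (big-M MILP `min Σ y_j` s.t.
`0 ≤ v_j ≤ M y_j`, `Σ v_j ≥ ε_tot`), or their Boolean analogue — activation
routes, support-minimal node sets whose exclusive activation is a fixed point
keeping the target on.  The solver is HiGHS, driven through
`scipy.optimize.milp` behind a solver-agnostic model container.

## Worked example

The bundled two-network case study (13 shared nodes; network A adds an
`r3 → C2` feedback absent from network B) ships with the package:

```sh
selnet fixtures --dest fx
selnet solve-selective fx/mkmn_a.rules fx/mkmn_b.rules \
    --target C9 --value-a 0 --value-b 1
```

prints (one JSON line per optimal solution):

```json
{"em_status": "other", "enforced": {"A:C6": 0, "B:C6": 0}, "objective": 1, "support": ["C6"], "verified_minimal": true}
{"em_status": "other", "enforced": {"A:C7": 0, "B:C7": 0}, "objective": 1, "support": ["C7"], "verified_minimal": true}
{"em_status": "other", "enforced": {"A:r3": 0, "B:r3": 0}, "objective": 1, "support": ["r3"], "verified_minimal": true}
```

Exactly three alternative optimal interventions exist, each inhibiting a
single node (`C6`, `C7` or `r3` clamped to 0), each certified support-minimal.
Every one switches C9 off in network A — where all activation routes funnel
through the `C6 & C7 → r3` branch — while network B keeps C9 on through its
two unaffected routes.  The route decomposition itself:

```python
>>> from selnet import make_mkmn_pair, boolean_activation_routes
>>> pair = make_mkmn_pair()
>>> [sorted(r) for r in boolean_activation_routes(pair.net_b, "C9")]
[['C6', 'C7', 'C9', 'r3'], ['C3', 'C4', 'C8', 'C9', 'r2'], ['C1', 'C2', 'C5', 'C9', 'r1', 'r4']]
>>> [sorted(r) for r in boolean_activation_routes(pair.net_a, "C9")]
[['C6', 'C7', 'C9', 'r3']]
```

Network B decomposes into three activation routes, network A into one — the
structural reason the selective intervention exists.

Other entry points: `selnet solve-single` (one network, one target value) and
`selnet validate-em` (steady-state feasibility and support-minimality report
for a reaction set of a stoichiometric model in TSV form).

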