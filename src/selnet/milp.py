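"""Mixed-integer linear encodings of Boolean-network intervention problems.

The central container is :class:`LinearProgram`, a solver-agnostic list of
variables, linear constraints and a linear objective.  Each network node i
contributes four binary decision variables:

* ``x_i``   — final value of the node after any perturbation,
* ``x̂_i``  — value computed by the (unperturbed) Boolean logic,
* ``u_i``   — perturbation flag (``u_i = 1`` iff node i is intervened on),
* ``z_i``   — value enforced on the node while it is perturbed,

linked by the exact linearization of ``x_i = (1-u_i)·x̂_i + u_i·z_i``.  Gates
are encoded with the standard big-M-free inequalities (k-ary AND/OR, NOT).
Gate inputs read the parents' *final* ``x`` values, so the feasible ``x``
vectors for a fixed ``(u, z)`` are exactly the fixed points of the perturbed
network: perturbed nodes clamped to ``z``, all others following their rules.
On multistable (cyclic) networks the solver is therefore free to select any
consistent fixed point — a deliberately permissive steady-state semantics.

The objective minimizes the number of perturbed nodes, ``min Σ u_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .boolnet import AND, LITERAL, NOT, OR, BooleanNetwork, NetworkPair

__all__ = [
    "LinearProgram", "Variable", "Constraint", "EncodingIndex", "ProblemSpec",
    "encode_gate", "encode_perturbation_linkage", "encode_shared_coupling",
    "build_steady_state_milp", "build_single_target_milp", "build_selective_milp",
]

_SENSES = ("<=", "=", ">=")


@dataclass(frozen=True)
class Variable:
    name: str
    lb: float
    ub: float
    integer: bool


@dataclass(frozen=True)
class Constraint:
    terms: tuple[tuple[str, float], ...]
    sense: str
    rhs: float
    name: str | None = None


def _combine(terms) -> tuple[tuple[str, float], ...]:
    """Normalize a term mapping/iterable, summing repeated variables."""
    acc: dict[str, float] = {}
    items = terms.items() if isinstance(terms, Mapping) else terms
    for var, coef in items:
        acc[var] = acc.get(var, 0.0) + float(coef)
    return tuple(acc.items())


class LinearProgram:
    """Variables, linear constraints and one linear objective.

    All binaries have bounds [0, 1]; every variable used in a constraint or
    the objective must have been declared first.
    """

    def __init__(self):
        self._variables: dict[str, Variable] = {}
        self.constraints: list[Constraint] = []
        self.objective: tuple[tuple[tuple[str, float], ...], str] = ((), "min")

    @property
    def variables(self) -> dict[str, Variable]:
        return self._variables

    def add_variable(self, name: str, lb: float = 0.0, ub: float = 1.0,
                     integer: bool = True) -> str:
        if name in self._variables:
            raise ValueError(f"duplicate variable {name!r}")
        self._variables[name] = Variable(name, float(lb), float(ub), integer)
        return name

    def add_binary(self, name: str) -> str:
        return self.add_variable(name, 0.0, 1.0, True)

    def add_continuous(self, name: str, lb: float, ub: float) -> str:
        return self.add_variable(name, lb, ub, False)

    def _check_terms(self, terms: tuple[tuple[str, float], ...]) -> None:
        for var, _ in terms:
            if var not in self._variables:
                raise ValueError(f"undeclared variable {var!r}")

    def add_constraint(self, terms, sense: str, rhs: float, name: str | None = None) -> None:
        if sense not in _SENSES:
            raise ValueError(f"bad sense {sense!r}")
        norm = _combine(terms)
        self._check_terms(norm)
        self.constraints.append(Constraint(norm, sense, float(rhs), name))

    def add_constraints(self, cons: Iterable) -> None:
        for terms, sense, rhs in cons:
            self.add_constraint(terms, sense, rhs)

    def set_objective(self, terms, direction: str = "min") -> None:
        if direction not in ("min", "max"):
            raise ValueError(f"bad objective direction {direction!r}")
        norm = _combine(terms)
        self._check_terms(norm)
        self.objective = (norm, direction)

    def copy(self) -> "LinearProgram":
        dup = LinearProgram()
        dup._variables = dict(self._variables)
        dup.constraints = list(self.constraints)
        dup.objective = self.objective
        return dup

    # ------------------------------------------------------------------
    def to_lp_string(self) -> str:
        """CPLEX LP-format text with the package's deterministic variable ids."""

        def side(terms):
            parts = []
            for var, coef in terms:
                sign = "+" if coef >= 0 else "-"
                parts.append(f"{sign} {abs(coef):g} {var}")
            return " ".join(parts) if parts else "0"

        obj_terms, direction = self.objective
        lines = ["Minimize" if direction == "min" else "Maximize",
                 f" obj: {side(obj_terms)}",
                 "Subject To"]
        for i, c in enumerate(self.constraints):
            op = {"<=": "<=", ">=": ">=", "=": "="}[c.sense]
            lines.append(f" {c.name or f'c{i}'}: {side(c.terms)} {op} {c.rhs:g}")
        cont = [v for v in self._variables.values() if not v.integer]
        if cont:
            lines.append("Bounds")
            for v in cont:
                lines.append(f" {v.lb:g} <= {v.name} <= {v.ub:g}")
        bins = [v.name for v in self._variables.values() if v.integer]
        if bins:
            lines.append("Binary")
            lines.append(" " + " ".join(bins))
        lines.append("End")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# constraint generators (returned as raw (terms, sense, rhs) tuples)


def encode_gate(kind: str, output_var: str, input_vars: list[str]) -> list:
    """Linear constraints whose unique feasible output equals the gate value.

    AND:  w <= a_i (all i),  w >= Σ a_i - (k-1)
    OR:   w >= a_i (all i),  w <= Σ a_i
    NOT:  w = 1 - a
    LITERAL: w = a
    """
    k = len(input_vars)
    if kind == AND:
        if k < 1:
            raise ValueError("AND gate needs at least one input")
        cons = [([(output_var, 1.0), (a, -1.0)], "<=", 0.0) for a in input_vars]
        tail = [(a, -1.0) for a in input_vars] + [(output_var, 1.0)]
        cons.append((tail, ">=", -(k - 1.0)))
        return cons
    if kind == OR:
        if k < 1:
            raise ValueError("OR gate needs at least one input")
        cons = [([(output_var, -1.0), (a, 1.0)], "<=", 0.0) for a in input_vars]
        tail = [(a, -1.0) for a in input_vars] + [(output_var, 1.0)]
        cons.append((tail, "<=", 0.0))
        return cons
    if kind == NOT:
        if k != 1:
            raise ValueError("NOT gate takes exactly one input")
        return [([(output_var, 1.0), (input_vars[0], 1.0)], "=", 1.0)]
    if kind == LITERAL:
        if k != 1:
            raise ValueError("LITERAL gate takes exactly one input")
        return [([(output_var, 1.0), (input_vars[0], -1.0)], "=", 0.0)]
    raise ValueError(f"unknown gate kind {kind!r}")


def encode_perturbation_linkage(x: str, xhat: str, u: str, z: str) -> list:
    """Exact linearization of ``x = (1-u)·x̂ + u·z`` for binaries.

    When ``u = 0`` the four inequalities force ``x = x̂`` (z free); when
    ``u = 1`` they force ``x = z`` (x̂ free).
    """
    return [
        ([(x, 1.0), (xhat, -1.0), (u, -1.0)], "<=", 0.0),
        ([(xhat, 1.0), (x, -1.0), (u, -1.0)], "<=", 0.0),
        ([(x, 1.0), (z, -1.0), (u, 1.0)], "<=", 1.0),
        ([(z, 1.0), (x, -1.0), (u, 1.0)], "<=", 1.0),
    ]


def encode_shared_coupling(x_a: str, x_b: str, u: str) -> list:
    """Force a shared node's final values equal across networks unless perturbed.

    When ``u = 0`` both inequalities reduce to ``x_A = x_B``; when ``u = 1``
    they impose nothing beyond the variable bounds.
    """
    return [
        ([(x_a, 1.0), (x_b, -1.0), (u, -1.0)], "<=", 0.0),
        ([(x_b, 1.0), (x_a, -1.0), (u, -1.0)], "<=", 0.0),
    ]


# ---------------------------------------------------------------------------
# problem construction


@dataclass(frozen=True)
class ProblemSpec:
    """Target node, desired values per network tag, and intervention semantics.

    ``tie_z = True`` (default) makes a perturbation one physical action: the
    enforced value of a shared perturbed node is identical in both networks.
    ``couple_states = True`` additionally forces *unperturbed* shared nodes to
    carry identical final values in both networks — a strict reading that
    disallows divergent downstream propagation and is off by default (see
    docs/methods.md).
    """

    target: str
    desired: Mapping[str, int]
    mode: str = "selective"
    tie_z: bool = True
    couple_states: bool = False

    def __post_init__(self):
        if self.mode not in ("single", "selective"):
            raise ValueError(f"bad mode {self.mode!r}")
        object.__setattr__(self, "desired", dict(self.desired))
        for tag, d in self.desired.items():
            if d not in (0, 1):
                raise ValueError(f"desired value for {tag!r} must be 0 or 1")
        if self.mode == "single" and len(self.desired) != 1:
            raise ValueError("single mode takes exactly one desired value")
        if self.mode == "selective" and len(self.desired) == 2:
            a, b = self.desired.values()
            if a == b:
                raise ValueError("selective mode requires opposite desired values")


@dataclass
class EncodingIndex:
    """Map from nodes to their decision-variable ids, per network tag.

    ``u`` is indexed once per node (shared across networks); gate auxiliaries
    are keyed by (tag, node, gate id).  Variable ids follow the deterministic
    ``{tag}.{node}.{role}`` pattern (``shared.{node}.u`` for the flags) so
    exported models are byte-for-byte reproducible.
    """

    tags: tuple[str, ...] = ()
    x: dict[tuple[str, str], str] = field(default_factory=dict)
    xhat: dict[tuple[str, str], str] = field(default_factory=dict)
    z: dict[tuple[str, str], str] = field(default_factory=dict)
    u: dict[str, str] = field(default_factory=dict)
    gate: dict[tuple[str, str, int], str] = field(default_factory=dict)
    nodes_by_tag: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def support_from_values(self, values: Mapping[str, float]) -> frozenset[str]:
        return frozenset(n for n, var in self.u.items() if values[var] > 0.5)

    def enforced_from_values(self, values: Mapping[str, float],
                             support: frozenset[str]) -> dict[tuple[str, str], int]:
        out = {}
        for tag in self.tags:
            for n in support:
                if (tag, n) in self.z:
                    out[(tag, n)] = int(round(values[self.z[(tag, n)]]))
        return out


def _encode_network(lp: LinearProgram, idx: EncodingIndex,
                    net: BooleanNetwork, tag: str) -> None:
    """Declare x/x̂/z per node, encode every rule's gates onto x̂, link via u."""
    idx.nodes_by_tag[tag] = net.nodes
    for node in net.nodes:
        idx.x[(tag, node)] = lp.add_binary(f"{tag}.{node}.x")
        idx.xhat[(tag, node)] = lp.add_binary(f"{tag}.{node}.xhat")
        idx.z[(tag, node)] = lp.add_binary(f"{tag}.{node}.z")
    for node in net.nodes:
        xhat = idx.xhat[(tag, node)]
        circ = net.rules.get(node)
        if circ is None:
            # unperturbed inputs sit at their declared default value
            lp.add_constraint([(xhat, 1.0)], "=", float(net.input_defaults[node]))
            continue
        gate_vars: list[str] = []
        for g in circ.gates:
            if g.gid == circ.output:
                wv = xhat
            else:
                wv = lp.add_binary(f"{tag}.{node}.g{g.gid}")
                idx.gate[(tag, node, g.gid)] = wv
            ins = [idx.x[(tag, r)] if isinstance(r, str) else gate_vars[r]
                   for r in g.inputs]
            lp.add_constraints(encode_gate(g.kind, wv, ins))
            gate_vars.append(wv)
    for node in net.nodes:
        lp.add_constraints(encode_perturbation_linkage(
            idx.x[(tag, node)], idx.xhat[(tag, node)],
            idx.u[node], idx.z[(tag, node)]))


def build_steady_state_milp(net: BooleanNetwork, tag: str = "A"
                            ) -> tuple[LinearProgram, EncodingIndex]:
    """Perturbed-steady-state system for one network, no target constraint.

    Feasible assignments are exactly: choose (u, z), then any fixed point of
    the network with the u-flagged nodes clamped to z.  Objective min Σ u.
    """
    lp = LinearProgram()
    idx = EncodingIndex(tags=(tag,))
    for node in net.nodes:
        idx.u[node] = lp.add_binary(f"shared.{node}.u")
    _encode_network(lp, idx, net, tag)
    lp.set_objective([(v, 1.0) for v in idx.u.values()], "min")
    return lp, idx


def build_single_target_milp(net: BooleanNetwork, spec: ProblemSpec
                             ) -> tuple[LinearProgram, EncodingIndex]:
    """Minimal-intervention MILP for one network: force the target to ``d``."""
    if spec.mode != "single":
        raise ValueError("spec.mode must be 'single'")
    if spec.target not in net.nodes:
        raise ValueError(f"target {spec.target!r} not in network")
    (tag, d), = spec.desired.items()
    lp, idx = build_steady_state_milp(net, tag)
    lp.add_constraint([(idx.x[(tag, spec.target)], 1.0)], "=", float(d), name="target")
    return lp, idx


def build_selective_milp(pair: NetworkPair, spec: ProblemSpec
                         ) -> tuple[LinearProgram, EncodingIndex]:
    """Selective-modulation MILP: one intervention, opposite target values.

    One ``u`` flag per node of V_A ∪ V_B; per-network x/x̂/z and gate systems;
    the target constraint is added in every network for which a desired value
    is given (a network may omit the target entirely).  With ``tie_z`` the
    enforced value of a shared perturbed node is a single decision; with
    ``couple_states`` the strict equality coupling of unperturbed shared nodes
    is added as well.
    """
    if spec.mode != "selective":
        raise ValueError("spec.mode must be 'selective'")
    nets = {"A": pair.net_a, "B": pair.net_b}
    for tag in spec.desired:
        if tag not in nets:
            raise ValueError(f"unknown network tag {tag!r}")
        if spec.target not in nets[tag].nodes:
            raise ValueError(
                f"target {spec.target!r} has a desired value for network {tag} "
                "but is absent from it")
    lp = LinearProgram()
    idx = EncodingIndex(tags=("A", "B"))
    union = list(pair.net_a.nodes) + [n for n in pair.net_b.nodes
                                      if n not in pair.shared]
    for node in union:
        idx.u[node] = lp.add_binary(f"shared.{node}.u")
    _encode_network(lp, idx, pair.net_a, "A")
    _encode_network(lp, idx, pair.net_b, "B")
    for node in sorted(pair.shared):
        if spec.tie_z:
            lp.add_constraint([(idx.z[("A", node)], 1.0),
                               (idx.z[("B", node)], -1.0)], "=", 0.0)
        if spec.couple_states:
            lp.add_constraints(encode_shared_coupling(
                idx.x[("A", node)], idx.x[("B", node)], idx.u[node]))
    for tag, d in spec.desired.items():
        lp.add_constraint([(idx.x[(tag, spec.target)], 1.0)], "=", float(d),
                          name=f"target_{tag}")
    lp.set_objective([(v, 1.0) for v in idx.u.values()], "min")
    return lp, idx
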