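"""Boolean regulatory networks: rule files, gate circuits, synchronous dynamics.

A network is a directed graph ``G(V, F)``: every node carries a binary state
and every non-input node an update rule ``f_i`` over its regulators, applied
synchronously, ``x_i(t+1) = f_i(x_{i1}(t), ..., x_{ik}(t))``.  Rules are kept
as small acyclic circuits of k-ary AND/OR gates, NOT gates and literal
pass-throughs so that they translate directly into linear constraints
(:mod:`selnet.milp`).

Rule-file dialect::

    # comment
    input C1            # source node, defaults to 1 ("available")
    input C3 = 0        # source node with an explicit default
    C2 = C1
    C9 = r4 | C8 | r3   # precedence: ! (NOT) > & (AND) > | (OR)

Names match ``[A-Za-z0-9_]+`` and are case-sensitive; node identity across
networks is by exact name.  Names that are referenced but never declared
become input nodes with default value 1 — the convention mirrors metabolic
usage, where source compounds are assumed available unless stated otherwise.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "AND", "OR", "NOT", "LITERAL",
    "Gate", "GateCircuit", "BooleanNetwork", "NetworkPair", "RuleParseError",
    "parse_rules", "serialize_rules", "network_to_json", "network_from_json",
    "synchronous_step", "is_fixed_point", "shared_nodes", "steady_state",
]

AND = "AND"
OR = "OR"
NOT = "NOT"
LITERAL = "LITERAL"
_GATE_KINDS = (AND, OR, NOT, LITERAL)

_NAME_RE = re.compile(r"[A-Za-z0-9_]+")
_INPUT_RE = re.compile(r"input\s+([A-Za-z0-9_]+)(?:\s*=\s*([01]))?\s*$")


class RuleParseError(ValueError):
    """Malformed rule file; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Gate:
    """One gate of a rule circuit.

    ``inputs`` entries are node names (``str``) or ids of *earlier* gates
    (``int``), so every circuit is acyclic by construction.
    """

    gid: int
    kind: str
    inputs: tuple

    def __post_init__(self):
        if self.kind not in _GATE_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind in (NOT, LITERAL) and len(self.inputs) != 1:
            raise ValueError(f"{self.kind} gate takes exactly one input")
        if self.kind in (AND, OR) and len(self.inputs) < 1:
            raise ValueError(f"{self.kind} gate needs at least one input")
        for ref in self.inputs:
            if isinstance(ref, int):
                if not 0 <= ref < self.gid:
                    raise ValueError("gate may only reference earlier gates")
            elif not isinstance(ref, str):
                raise TypeError("gate input must be a node name or gate id")


@dataclass(frozen=True)
class GateCircuit:
    """An acyclic gate circuit computing one node's update value."""

    gates: tuple[Gate, ...]
    output: int

    def __post_init__(self):
        for i, g in enumerate(self.gates):
            if g.gid != i:
                raise ValueError("gate ids must equal their position")
        if not 0 <= self.output < len(self.gates):
            raise ValueError("output must reference a gate of the circuit")

    def evaluate(self, values: Mapping[str, int]) -> int:
        vals: list[int] = []
        for g in self.gates:
            ins = [values[r] if isinstance(r, str) else vals[r] for r in g.inputs]
            if g.kind == AND:
                v = int(all(ins))
            elif g.kind == OR:
                v = int(any(ins))
            elif g.kind == NOT:
                v = 1 - ins[0]
            else:  # LITERAL
                v = ins[0]
            vals.append(v)
        return vals[self.output]

    def referenced_nodes(self) -> tuple[str, ...]:
        """Node names read by the circuit, in first-reference order."""
        seen: dict[str, None] = {}
        for g in self.gates:
            for r in g.inputs:
                if isinstance(r, str):
                    seen.setdefault(r)
        return tuple(seen)

    def gate_census(self) -> dict[str, int]:
        census = {k: 0 for k in _GATE_KINDS}
        for g in self.gates:
            census[g.kind] += 1
        return census

    # expression unparsing; precedence: OR < AND < NOT < atom
    def to_expression(self) -> str:
        return self._expr(self.output, 0)

    def _expr(self, ref, parent_prec: int) -> str:
        if isinstance(ref, str):
            return ref
        g = self.gates[ref]
        if g.kind == LITERAL:
            return self._expr(g.inputs[0], parent_prec)
        if g.kind == NOT:
            return "!" + self._expr(g.inputs[0], 3)
        prec = 2 if g.kind == AND else 1
        op = " & " if g.kind == AND else " | "
        body = op.join(self._expr(r, prec) for r in g.inputs)
        return f"({body})" if prec < parent_prec else body


@dataclass
class BooleanNetwork:
    """Named nodes with gate-circuit update rules.

    ``nodes`` fixes iteration order; nodes without a rule are inputs and hold
    whatever value the state assigns them (``input_defaults`` supplies their
    unperturbed value).
    """

    nodes: tuple[str, ...]
    rules: dict[str, GateCircuit]
    input_defaults: dict[str, int]
    _topo: tuple[str, ...] | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        for name, circ in self.rules.items():
            if name not in node_set:
                raise ValueError(f"rule for undeclared node {name!r}")
            missing = set(circ.referenced_nodes()) - node_set
            if missing:
                raise ValueError(f"rule for {name!r} references unknown nodes {sorted(missing)}")
        inputs = set(self.inputs)
        if set(self.input_defaults) != inputs:
            raise ValueError("input_defaults must cover exactly the input nodes")
        for v in self.input_defaults.values():
            if v not in (0, 1):
                raise ValueError("input defaults must be 0 or 1")

    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if n not in self.rules)

    def parents(self, node: str) -> tuple[str, ...]:
        circ = self.rules.get(node)
        return circ.referenced_nodes() if circ is not None else ()

    def topological_order(self) -> tuple[str, ...] | None:
        """Nodes ordered parents-first, or ``None`` if the wiring is cyclic."""
        if self._topo is not None:
            return self._topo
        indeg = {n: len(set(self.parents(n))) for n in self.nodes}
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for n in self.nodes:
            for p in set(self.parents(n)):
                children[p].append(n)
        ready = [n for n in self.nodes if indeg[n] == 0]
        order: list[str] = []
        while ready:
            n = ready.pop()
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.nodes):
            return None
        self._topo = tuple(order)
        return self._topo


@dataclass
class NetworkPair:
    """Two structurally similar networks; ``shared`` is always computed."""

    net_a: BooleanNetwork
    net_b: BooleanNetwork
    shared: frozenset[str] = field(init=False)

    def __post_init__(self):
        self.shared = shared_nodes(self.net_a, self.net_b)


# ---------------------------------------------------------------------------
# rule-file parsing


def _tokenize(expr: str, line: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    i = 0
    while i < len(expr):
        ch = expr[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "&|!()":
            tokens.append(("op", ch))
            i += 1
            continue
        m = _NAME_RE.match(expr, i)
        if not m:
            raise RuleParseError(f"unexpected character {ch!r} in expression", line)
        tokens.append(("name", m.group()))
        i = m.end()
    return tokens


class _ExprParser:
    """Recursive descent for  expr := term ('|' term)* ;  term := factor ('&' factor)* ;
    factor := '!' factor | '(' expr ')' | NAME.  Same-level chains stay k-ary."""

    def __init__(self, tokens: list[tuple[str, str]], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _take(self):
        tok = self._peek()
        if tok is None:
            raise RuleParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self):
        ast = self._expr()
        if self._peek() is not None:
            raise RuleParseError(f"trailing tokens after expression", self.line)
        return ast

    def _expr(self):
        terms = [self._term()]
        while self._peek() == ("op", "|"):
            self._take()
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def _term(self):
        factors = [self._factor()]
        while self._peek() == ("op", "&"):
            self._take()
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def _factor(self):
        tok = self._take()
        if tok == ("op", "!"):
            return ("not", self._factor())
        if tok == ("op", "("):
            inner = self._expr()
            if self._take() != ("op", ")"):
                raise RuleParseError("expected ')'", self.line)
            return inner
        if tok[0] == "name":
            return ("lit", tok[1])
        raise RuleParseError(f"unexpected token {tok[1]!r}", self.line)


def _compile(ast) -> GateCircuit:
    gates: list[Gate] = []

    def emit(kind: str, inputs: list) -> int:
        gates.append(Gate(len(gates), kind, tuple(inputs)))
        return len(gates) - 1

    def rec(node):
        tag = node[0]
        if tag == "lit":
            return node[1]
        if tag == "not":
            return emit(NOT, [rec(node[1])])
        refs = [rec(c) for c in node[1]]
        return emit(AND if tag == "and" else OR, refs)

    out = rec(ast)
    if isinstance(out, str):
        out = emit(LITERAL, [out])
    return GateCircuit(tuple(gates), out)


def parse_expression(expr: str, line: int = 0) -> GateCircuit:
    """Compile a single rule expression into a gate circuit."""
    tokens = _tokenize(expr, line)
    if not tokens:
        raise RuleParseError("empty expression", line)
    return _compile(_ExprParser(tokens, line).parse())


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a rule file into a :class:`BooleanNetwork`.

    Undeclared referenced names are auto-declared as inputs with default 1.
    Raises :class:`RuleParseError` on syntax errors, duplicate rules, or an
    empty file.
    """
    declared_inputs: dict[str, int] = {}
    rules: dict[str, GateCircuit] = {}
    order: list[str] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _INPUT_RE.match(line)
        if m:
            name, dflt = m.group(1), int(m.group(2) or 1)
            if name in declared_inputs or name in rules:
                raise RuleParseError(f"duplicate declaration of {name!r}", ln)
            declared_inputs[name] = dflt
            order.append(name)
            continue
        if "=" not in line:
            raise RuleParseError("expected 'name = expression' or 'input name'", ln)
        lhs, rhs = line.split("=", 1)
        name = lhs.strip()
        if not _NAME_RE.fullmatch(name):
            raise RuleParseError(f"invalid node name {lhs.strip()!r}", ln)
        if name in rules or name in declared_inputs:
            raise RuleParseError(f"duplicate rule for {name!r}", ln)
        rules[name] = parse_expression(rhs, ln)
        order.append(name)
    if not order:
        raise RuleParseError("empty rule file")
    # auto-declare referenced-but-undefined names as available inputs
    for name in list(order):
        if name in rules:
            for ref in rules[name].referenced_nodes():
                if ref not in rules and ref not in declared_inputs:
                    declared_inputs[ref] = 1
                    order.append(ref)
    return BooleanNetwork(tuple(order), rules, declared_inputs)


def serialize_rules(net: BooleanNetwork) -> str:
    """Rule-file text that reparses to an equivalent network."""
    lines = []
    for n in net.nodes:
        if n in net.rules:
            lines.append(f"{n} = {net.rules[n].to_expression()}")
        else:
            lines.append(f"input {n} = {net.input_defaults[n]}")
    return "\n".join(lines) + "\n"


def network_to_json(net: BooleanNetwork) -> str:
    doc = {
        "nodes": list(net.nodes),
        "rules": {n: net.rules[n].to_expression() for n in net.nodes if n in net.rules},
        "inputs": {n: net.input_defaults[n] for n in net.inputs},
    }
    return json.dumps(doc, indent=2)


def network_from_json(text: str) -> BooleanNetwork:
    doc = json.loads(text)
    rules = {n: parse_expression(e) for n, e in doc["rules"].items()}
    return BooleanNetwork(tuple(doc["nodes"]), rules, {n: int(v) for n, v in doc["inputs"].items()})


# ---------------------------------------------------------------------------
# dynamics


def _check_state(net: BooleanNetwork, state: Mapping[str, int]) -> None:
    if set(state) != set(net.nodes):
        raise ValueError("state must cover exactly the network's nodes")


def synchronous_step(net: BooleanNetwork, state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update; input nodes keep their current value."""
    _check_state(net, state)
    return {
        n: net.rules[n].evaluate(state) if n in net.rules else state[n]
        for n in net.nodes
    }


def is_fixed_point(net: BooleanNetwork, state: Mapping[str, int]) -> bool:
    _check_state(net, state)
    return all(
        net.rules[n].evaluate(state) == state[n]
        for n in net.nodes
        if n in net.rules
    )


def shared_nodes(a: BooleanNetwork, b: BooleanNetwork) -> frozenset[str]:
    return frozenset(a.nodes) & frozenset(b.nodes)


def steady_state(
    net: BooleanNetwork,
    clamps: Mapping[str, int] | None = None,
    max_iter: int | None = None,
) -> dict[str, int] | None:
    """A fixed point of the network with ``clamps`` held at fixed values.

    Unclamped inputs sit at their defaults.  On acyclic wiring the fixed point
    is unique and computed exactly in one topological sweep; on cyclic wiring
    the state is iterated synchronously and ``None`` is returned if it fails to
    settle (a fixed point may then still exist on another trajectory).
    """
    clamps = dict(clamps or {})
    unknown = set(clamps) - set(net.nodes)
    if unknown:
        raise ValueError(f"clamped nodes not in network: {sorted(unknown)}")
    topo = net.topological_order()
    if topo is not None:
        s: dict[str, int] = {}
        for n in topo:
            if n in clamps:
                s[n] = clamps[n]
            elif n in net.rules:
                s[n] = net.rules[n].evaluate(s)
            else:
                s[n] = net.input_defaults[n]
        return {n: s[n] for n in net.nodes}
    # cyclic: iterate, re-imposing clamps after every sweep
    s = {n: net.input_defaults.get(n, 0) for n in net.nodes}
    s.update(clamps)
    limit = max_iter if max_iter is not None else 2 * len(net.nodes) + 4
    for _ in range(limit):
        nxt = synchronous_step(net, s)
        nxt.update(clamps)
        if nxt == s:
            return s
        s = nxt
    return None
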