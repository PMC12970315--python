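"""Gate/linkage constraint systems and problem construction."""

from itertools import product

import pytest

from helpers import feasible_assignments
from selnet.boolnet import parse_rules
from selnet.milp import (
    LinearProgram, ProblemSpec, build_selective_milp, build_single_target_milp,
    build_steady_state_milp, encode_gate, encode_perturbation_linkage,
    encode_shared_coupling,
)
from selnet.solve import enumerate_optimal_supports, solve


class TestLinearProgram:
    def test_duplicate_variable_rejected(self):
        lp = LinearProgram()
        lp.add_binary("x")
        with pytest.raises(ValueError):
            lp.add_binary("x")

    def test_undeclared_variable_rejected(self):
        lp = LinearProgram()
        lp.add_binary("x")
        with pytest.raises(ValueError):
            lp.add_constraint([("y", 1.0)], "<=", 1.0)
        with pytest.raises(ValueError):
            lp.set_objective([("y", 1.0)])

    def test_lp_export_is_deterministic_and_named(self):
        def build():
            net = parse_rules("input a = 1\nt = a")
            lp, _ = build_single_target_milp(
                net, ProblemSpec("t", {"A": 0}, mode="single"))
            return lp.to_lp_string()

        text = build()
        assert text == build()
        assert "shared.t.u" in text and "A.t.x" in text
        assert text.startswith("Minimize") and text.rstrip().endswith("End")


class TestGateEncoding:
    def test_and_conjunction_forced(self):
        cons = encode_gate("AND", "w", ["a", "b"])
        feas = feasible_assignments(cons, ["w", "a", "b"])
        assert {(e["a"], e["b"], e["w"]) for e in feas} == \
            {(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 1)}

    def test_or_disjunction_forced(self):
        cons = encode_gate("OR", "w", ["a", "b", "c"])
        for env in feasible_assignments(cons, ["w", "a", "b", "c"]):
            assert env["w"] == int(env["a"] or env["b"] or env["c"])

    def test_arity_and_kind_errors(self):
        with pytest.raises(ValueError):
            encode_gate("NOT", "w", ["a", "b"])
        with pytest.raises(ValueError):
            encode_gate("AND", "w", [])
        with pytest.raises(ValueError):
            encode_gate("XOR", "w", ["a", "b"])

    def test_linkage_u0_forces_logic_value(self):
        cons = encode_perturbation_linkage("x", "xh", "u", "z")
        feas = [e for e in feasible_assignments(cons, ["x", "xh", "u", "z"])
                if e["u"] == 0 and e["xh"] == 1]
        assert feas and all(e["x"] == 1 for e in feas)
        assert {e["z"] for e in feas} == {0, 1}  # z free

    def test_linkage_u1_forces_enforced_value(self):
        cons = encode_perturbation_linkage("x", "xh", "u", "z")
        feas = [e for e in feasible_assignments(cons, ["x", "xh", "u", "z"])
                if e["u"] == 1 and e["z"] == 0]
        assert feas and all(e["x"] == 0 for e in feas)
        assert {e["xh"] for e in feas} == {0, 1}  # logic value free

    def test_coupling_unperturbed_equality(self):
        cons = encode_shared_coupling("xa", "xb", "u")
        feas = feasible_assignments(cons, ["xa", "xb", "u"])
        got0 = {(e["xa"], e["xb"]) for e in feas if e["u"] == 0}
        got1 = {(e["xa"], e["xb"]) for e in feas if e["u"] == 1}
        assert got0 == {(0, 0), (1, 1)}
        assert got1 == {(0, 0), (0, 1), (1, 0), (1, 1)}


def perturbed_fixed_points(net, u, z):
    """Reference semantics: fixed points with u-flagged nodes clamped to z."""
    fps = []
    for bits in product((0, 1), repeat=len(net.nodes)):
        x = dict(zip(net.nodes, bits))
        ok = True
        for n in net.nodes:
            if u[n]:
                ok = x[n] == z[n]
            elif n in net.rules:
                ok = x[n] == net.rules[n].evaluate(x)
            else:
                ok = x[n] == net.input_defaults[n]
            if not ok:
                break
        if ok:
            fps.append(bits)
    return sorted(fps)


class TestEncodingSoundness:
    @pytest.mark.parametrize("text", [
        "input a = 1\nb = a\nt = !a & b",
        "input a = 0\nt = a | b\nb = !t",   # 2-cycle through t
        "x = !x",                            # no fixed point at u=0
        "input a = 1\nt = a & a",            # repeated literal
    ])
    def test_feasible_x_equals_perturbed_fixed_points(self, text):
        """For every (u, z), the encoding's feasible x vectors are exactly the
        fixed points of the clamped network (exhaustive check)."""
        net = parse_rules(text)
        lp, idx = build_steady_state_milp(net)
        nodes = net.nodes
        for ubits in product((0, 1), repeat=len(nodes)):
            for zbits in product((0, 1), repeat=len(nodes)):
                u = dict(zip(nodes, ubits))
                z = dict(zip(nodes, zbits))
                feas = []
                for xbits in product((0, 1), repeat=len(nodes)):
                    x = dict(zip(nodes, xbits))
                    env = {idx.u[n]: u[n] for n in nodes}
                    env.update({idx.x[("A", n)]: x[n] for n in nodes})
                    env.update({idx.z[("A", n)]: z[n] for n in nodes})
                    # gate outputs are functions of x, so x̂ is determined
                    for n in nodes:
                        circ = net.rules.get(n)
                        env[idx.xhat[("A", n)]] = (
                            circ.evaluate(x) if circ else net.input_defaults[n])
                        if circ:
                            vals = []
                            for g in circ.gates:
                                ins = [x[r] if isinstance(r, str) else vals[r]
                                       for r in g.inputs]
                                v = {"AND": lambda: int(all(ins)),
                                     "OR": lambda: int(any(ins)),
                                     "NOT": lambda: 1 - ins[0],
                                     "LITERAL": lambda: ins[0]}[g.kind]()
                                vals.append(v)
                                if (("A", n, g.gid)) in idx.gate:
                                    env[idx.gate[("A", n, g.gid)]] = v
                    raw = [(dict(c.terms), c.sense, c.rhs) for c in lp.constraints]
                    from helpers import _satisfied
                    if all(_satisfied(c, env) for c in raw):
                        feas.append(xbits)
                assert sorted(feas) == perturbed_fixed_points(net, u, z)

    def test_objective_counts_support(self):
        net = parse_rules("input a = 1\nb = a\nt = b")
        lp, idx = build_single_target_milp(
            net, ProblemSpec("t", {"A": 0}, mode="single"))
        res = solve(lp)
        support = idx.support_from_values(res.values)
        assert res.objective == len(support) == 1


class TestProblemConstruction:
    def test_already_satisfied_target_needs_nothing(self):
        net = parse_rules("input a = 1\nt = a")
        lp, idx = build_single_target_milp(
            net, ProblemSpec("t", {"A": 1}, mode="single"))
        pool = enumerate_optimal_supports(lp, idx)
        assert [s.support for s in pool] == [frozenset()]
        assert pool[0].objective == 0

    def test_two_node_repression_supports(self):
        net = parse_rules("input a = 1\nt = a")
        lp, idx = build_single_target_milp(
            net, ProblemSpec("t", {"A": 0}, mode="single"))
        pool = enumerate_optimal_supports(lp, idx)
        assert {s.support for s in pool} == {frozenset({"a"}), frozenset({"t"})}

    def test_chain_has_three_alternative_optima(self):
        net = parse_rules("input a = 1\nb = a\nt = b")
        lp, idx = build_single_target_milp(
            net, ProblemSpec("t", {"A": 0}, mode="single"))
        pool = enumerate_optimal_supports(lp, idx)
        assert all(s.objective == 1 for s in pool)
        assert {s.support for s in pool} == {
            frozenset({"a"}), frozenset({"b"}), frozenset({"t"})}

    def test_missing_target_rejected(self):
        net = parse_rules("input a = 1\nt = a")
        with pytest.raises(ValueError):
            build_single_target_milp(
                net, ProblemSpec("zz", {"A": 0}, mode="single"))

    def test_selective_requires_opposite_values(self):
        with pytest.raises(ValueError):
            ProblemSpec("t", {"A": 1, "B": 1}, mode="selective")

    def test_identical_networks_tie_z_infeasible(self):
        from selnet.boolnet import NetworkPair
        net = parse_rules("input a = 1\nb = a\nt = b")
        pair = NetworkPair(net, parse_rules("input a = 1\nb = a\nt = b"))
        lp, idx = build_selective_milp(
            pair, ProblemSpec("t", {"A": 0, "B": 1}, tie_z=True))
        assert solve(lp).status == "infeasible"

    def test_target_unique_to_one_network(self):
        """A network lacking the target simply gets no target constraint."""
        from selnet.boolnet import NetworkPair
        net_a = parse_rules("input a = 1\nt = a")
        net_b = parse_rules("input a = 1\nq = a")
        pair = NetworkPair(net_a, net_b)
        lp, idx = build_selective_milp(
            pair, ProblemSpec("t", {"A": 0}, mode="selective"))
        pool = enumerate_optimal_supports(lp, idx)
        assert {s.support for s in pool} == {frozenset({"a"}), frozenset({"t"})}
        # but demanding a value for t in B is an input error
        with pytest.raises(ValueError):
            build_selective_milp(pair, ProblemSpec("t", {"A": 0, "B": 1}))

    def test_state_coupling_only_shrinks_feasible_set(self):
        """Removing the strict coupling can only enlarge the solution set."""
        from selnet.boolnet import NetworkPair
        from selnet.fixtures import make_mkmn_pair
        pair = make_mkmn_pair()
        free = build_selective_milp(
            pair, ProblemSpec("C9", {"A": 0, "B": 1}, couple_states=False))
        strict = build_selective_milp(
            pair, ProblemSpec("C9", {"A": 0, "B": 1}, couple_states=True))
        pool_free = enumerate_optimal_supports(*free)
        res_strict = solve(strict[0])
        assert len(pool_free) == 3
        # strict reading: every diverging downstream node needs u = 1, and
        # tied z then contradicts the opposite target values outright
        assert res_strict.status == "infeasible"
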