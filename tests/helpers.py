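"""Independent brute-force oracles and small enumeration utilities.

These deliberately avoid the MILP path: interventions are checked by direct
fixed-point computation (clamp, then settle the network), and constraint
systems by exhaustive 0/1 assignment.  They are exact on acyclic networks,
where a clamped configuration has a unique fixed point.
"""

from itertools import combinations, product

from selnet.boolnet import steady_state


def _clamped_ok(net, clamps, target, desired):
    local = {k: v for k, v in clamps.items() if k in net.nodes}
    fp = steady_state(net, local)
    if fp is None:
        return False
    if target not in net.nodes or desired is None:
        return True
    return fp[target] == desired


def brute_force_single(net, target, desired, max_size=None):
    """(optimal size, set of optimal supports) by exhaustive search over all
    (support, enforced-value) interventions, smallest supports first."""
    nodes = list(net.nodes)
    cap = max_size if max_size is not None else len(nodes)
    for size in range(0, cap + 1):
        found = set()
        for comb in combinations(nodes, size):
            for zvals in product((0, 1), repeat=size):
                if _clamped_ok(net, dict(zip(comb, zvals)), target, desired):
                    found.add(frozenset(comb))
                    break
        if found:
            return size, found
    return None, set()


def brute_force_selective(pair, target, d_a, d_b, tie_z=True, max_size=None):
    """Oracle for the selective problem: one support over V_A ∪ V_B, enforced
    values shared (tie_z) or free per network, fixed-point check per network."""
    union = list(dict.fromkeys(list(pair.net_a.nodes) + list(pair.net_b.nodes)))
    cap = max_size if max_size is not None else len(union)

    def feasible(comb):
        k = len(comb)
        if tie_z:
            z_space = (dict(zip(comb, z)) for z in product((0, 1), repeat=k))
            for clamps in z_space:
                if (_clamped_ok(pair.net_a, clamps, target, d_a)
                        and _clamped_ok(pair.net_b, clamps, target, d_b)):
                    return True
            return False
        for za in product((0, 1), repeat=k):
            if not _clamped_ok(pair.net_a, dict(zip(comb, za)), target, d_a):
                continue
            for zb in product((0, 1), repeat=k):
                if _clamped_ok(pair.net_b, dict(zip(comb, zb)), target, d_b):
                    return True
        return False

    for size in range(0, cap + 1):
        found = {frozenset(c) for c in combinations(union, size) if feasible(c)}
        if found:
            return size, found
    return None, set()


def feasible_assignments(constraint_tuples, var_names):
    """All 0/1 assignments of ``var_names`` satisfying the raw constraints."""
    sols = []
    for assign in product((0, 1), repeat=len(var_names)):
        env = dict(zip(var_names, assign))
        if all(_satisfied(c, env) for c in constraint_tuples):
            sols.append(env)
    return sols


def _satisfied(con, env):
    terms, sense, rhs = con
    items = terms.items() if isinstance(terms, dict) else terms
    lhs = sum(coef * env[var] for var, coef in items)
    if sense == "<=":
        return lhs <= rhs + 1e-9
    if sense == ">=":
        return lhs >= rhs - 1e-9
    return abs(lhs - rhs) <= 1e-9
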