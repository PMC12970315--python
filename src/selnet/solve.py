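"""Solve and enumerate: HiGHS adapter, solution pools, the subset-scan workflow.

The adapter drives the HiGHS branch-and-cut solver through
:func:`scipy.optimize.milp` behind a stable contract: proven optimality or
proven infeasibility, integer feasibility at tolerance 1e-6, and deterministic
output (HiGHS run single-threaded through scipy is deterministic for a fixed
model; enumeration output is additionally sorted, so solution order never
depends on solver internals).

Alternative optima are enumerated with support-based no-good (exclusion)
cuts: after an incumbent with support S, the cut

    Σ_{i∈S} u_i − Σ_{i∉S} u_i ≤ |S| − 1

removes exactly the supports equal to S (supersets survive) and the model is
re-solved until the objective rises past the bound.  Solutions over the same
support that differ only in enforced values z are collapsed into a single
:class:`InterventionSolution` carrying the first-found z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .milp import EncodingIndex, LinearProgram

__all__ = [
    "SolverConfig", "SolverError", "SolveResult", "InterventionSolution",
    "SolutionPool", "solve", "enumerate_optimal_supports", "enumerate_ranked",
    "subset_scan", "exclusion_cut",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
FEASIBLE_LIMIT = "feasible-limit"


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Adapter settings.  ``seed`` is recorded in logs for provenance; the
    HiGHS build behind scipy exposes no randomization, so runs are repeatable
    regardless.  ``int_tol`` is the integer feasibility tolerance."""

    seed: int = 0
    time_limit: float | None = None
    int_tol: float = 1e-6


@dataclass
class SolveResult:
    status: str  # optimal | infeasible | feasible-limit
    objective: float | None
    values: dict[str, float] | None


@dataclass
class InterventionSolution:
    """A candidate intervention: support S with enforced states per network."""

    support: frozenset[str]
    enforced: dict[tuple[str, str], int]
    objective: int
    verified_minimal: bool | None = None
    em_status: str = "unchecked"  # em_in_A_only | other | unchecked

    def sort_key(self):
        return (self.objective, tuple(sorted(self.support)))

    def to_dict(self) -> dict:
        return {
            "support": sorted(self.support),
            "enforced": {f"{tag}:{node}": v
                         for (tag, node), v in sorted(self.enforced.items())},
            "objective": self.objective,
            "verified_minimal": self.verified_minimal,
            "em_status": self.em_status,
        }


class SolutionPool(list):
    """List of :class:`InterventionSolution`; ``complete`` is False when the
    enumeration stopped at the solution limit."""

    def __init__(self, items=(), complete: bool = True):
        super().__init__(items)
        self.complete = complete


def solve(lp: LinearProgram, config: SolverConfig | None = None,
          fixed: Mapping[str, float] | None = None) -> SolveResult:
    """Solve to proven optimality or infeasibility.

    ``fixed`` pins variables by shrinking their bounds — used by the
    minimality re-solves and by tests; the model itself is not mutated.
    """
    config = config or SolverConfig()
    names = list(lp.variables)
    if not names:
        return SolveResult(OPTIMAL, 0.0, {})
    pos = {n: i for i, n in enumerate(names)}
    nvar = len(names)

    obj_terms, direction = lp.objective
    c = np.zeros(nvar)
    for var, coef in obj_terms:
        c[pos[var]] += coef
    sign = 1.0 if direction == "min" else -1.0

    lb = np.array([lp.variables[n].lb for n in names])
    ub = np.array([lp.variables[n].ub for n in names])
    if fixed:
        for var, val in fixed.items():
            lb[pos[var]] = ub[pos[var]] = float(val)
    integrality = np.array([1 if lp.variables[n].integer else 0 for n in names])

    constraints = None
    if lp.constraints:
        rows, cols, data = [], [], []
        cl = np.empty(len(lp.constraints))
        cu = np.empty(len(lp.constraints))
        for i, con in enumerate(lp.constraints):
            for var, coef in con.terms:
                rows.append(i)
                cols.append(pos[var])
                data.append(coef)
            if con.sense == "<=":
                cl[i], cu[i] = -np.inf, con.rhs
            elif con.sense == ">=":
                cl[i], cu[i] = con.rhs, np.inf
            else:
                cl[i] = cu[i] = con.rhs
        a_mat = sparse.csr_matrix((data, (rows, cols)),
                                  shape=(len(lp.constraints), nvar))
        constraints = LinearConstraint(a_mat, cl, cu)

    options: dict = {"presolve": True, "mip_rel_gap": 0.0}
    if config.time_limit is not None:
        options["time_limit"] = config.time_limit
    res = milp(c=sign * c, constraints=constraints, integrality=integrality,
               bounds=Bounds(lb, ub), options=options)

    if res.status == 0:
        status = OPTIMAL
    elif res.status == 2:
        return SolveResult(INFEASIBLE, None, None)
    elif res.status == 1:
        if res.x is None:
            return SolveResult(FEASIBLE_LIMIT, None, None)
        status = FEASIBLE_LIMIT
    else:
        raise SolverError(f"solver returned status {res.status}: {res.message}")

    values: dict[str, float] = {}
    for n, v in zip(names, res.x):
        if lp.variables[n].integer:
            r = round(v)
            if abs(v - r) > config.int_tol * 10 + 1e-5:
                raise SolverError(f"variable {n} not integral: {v}")
            values[n] = float(r)
        else:
            values[n] = float(v)
    objective = sum(coef * values[var] for var, coef in obj_terms)
    return SolveResult(status, objective, values)


# ---------------------------------------------------------------------------
# enumeration


def exclusion_cut(index: EncodingIndex, support: frozenset[str]):
    """Support-based no-good cut removing exactly the given u-pattern."""
    terms = [(var, 1.0 if node in support else -1.0)
             for node, var in index.u.items()]
    return terms, "<=", float(len(support) - 1)


def _extract(index: EncodingIndex, result: SolveResult) -> InterventionSolution:
    support = index.support_from_values(result.values)
    return InterventionSolution(
        support=support,
        enforced=index.enforced_from_values(result.values, support),
        objective=int(round(sum(result.values[v] for v in index.u.values()))),
    )


def _enumerate(lp: LinearProgram, index: EncodingIndex, stop_above,
               limit: int, config: SolverConfig | None) -> SolutionPool:
    work = lp.copy()
    pool = SolutionPool()
    res = solve(work, config)
    if res.status == INFEASIBLE:
        return pool
    if res.status == FEASIBLE_LIMIT:
        raise SolverError("time limit hit before proving the optimum")
    bound = stop_above(int(round(res.objective)))
    while True:
        if int(round(res.objective)) > bound:
            break
        pool.append(_extract(index, res))
        if len(pool) >= limit:
            pool.complete = False
            break
        work.add_constraint(*exclusion_cut(index, pool[-1].support))
        res = solve(work, config)
        if res.status == INFEASIBLE:
            break
        if res.status == FEASIBLE_LIMIT:
            raise SolverError("time limit hit during enumeration")
    pool.sort(key=InterventionSolution.sort_key)
    return pool


def enumerate_optimal_supports(lp: LinearProgram, index: EncodingIndex,
                               limit: int = 10_000,
                               config: SolverConfig | None = None) -> SolutionPool:
    """All distinct optimal supports, sorted lexicographically."""
    return _enumerate(lp, index, lambda first: first, limit, config)


def enumerate_ranked(lp: LinearProgram, index: EncodingIndex,
                     max_objective: int, limit: int = 10_000,
                     config: SolverConfig | None = None) -> SolutionPool:
    """Exclusion-cut enumeration continued past the optimum up to
    ``max_objective``; sorted by (objective, lexicographic support)."""
    return _enumerate(lp, index, lambda first: max_objective, limit, config)


def subset_scan(solutions_a, solutions_b) -> InterventionSolution | None:
    """First network-A solution whose support is contained in some network-B
    solution's support (subset includes equality), scanning A by objective."""
    b_supports = [sol.support for sol in solutions_b]
    for sol in sorted(solutions_a, key=InterventionSolution.sort_key):
        if any(sol.support <= s for s in b_supports):
            return sol
    return None
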