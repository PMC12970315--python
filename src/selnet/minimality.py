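"""Support-minimality verification by single-element-removal re-solves.

A candidate support S is minimal (at depth 1) when fixing ``u_i = 1`` for the
kept elements of S, ``u_i = 0`` everywhere else, and dropping any one element
of S leaves the target constraints unsatisfiable.  The flags outside S are
clamped to 0 during every re-solve: without that clamp the solver could
substitute fresh nodes for the removed one and the test would never certify
anything.  ``depth`` extends the test to removals of up to that many elements
for stricter minimality.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

from .milp import EncodingIndex, LinearProgram
from .solve import FEASIBLE_LIMIT, OPTIMAL, SolverConfig, SolverError, solve

__all__ = ["verify_support_minimality"]


def verify_support_minimality(lp: LinearProgram, index: EncodingIndex,
                              support: Iterable[str],
                              config: SolverConfig | None = None,
                              depth: int = 1) -> bool:
    """True iff no removal of up to ``depth`` elements of ``support`` leaves
    the problem feasible with the remaining support fixed.

    The empty support is vacuously minimal.  Solver failures propagate.
    """
    support = frozenset(support)
    if not support:
        return True
    unknown = support - set(index.u)
    if unknown:
        raise ValueError(f"support nodes without u variables: {sorted(unknown)}")
    base = {var: 0.0 for node, var in index.u.items() if node not in support}
    for r in range(1, min(depth, len(support)) + 1):
        for removed in combinations(sorted(support), r):
            fixed = dict(base)
            for node in support:
                fixed[index.u[node]] = 0.0 if node in removed else 1.0
            res = solve(lp, config, fixed=fixed)
            if res.status == OPTIMAL:
                return False
            if res.status == FEASIBLE_LIMIT:
                raise SolverError("time limit during minimality re-solve")
    return True
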