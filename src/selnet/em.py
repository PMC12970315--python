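"""Elementary-mode machinery for post-hoc validation of interventions.

An elementary mode (EM) of a stoichiometric matrix ``N`` (species × reactions)
is a nonzero flux vector ``v ≥ 0`` with ``N v = 0`` on balanced species whose
support is minimal: no nonzero steady flux exists on a strict subset of its
active reactions.  Two complementary tools live here:

* the stoichiometric MILP/LP formalism — steady-state feasibility of a
  candidate support S (big-M linking ``0 ≤ v_j ≤ M y_j`` plus a total-flux
  floor ``Σ v_j ≥ ε_tot``) and the support-minimality MILP
  ``min Σ y_j`` confined to S, plus a brute-force EM enumerator used as an
  oracle at small scale;
* Boolean activation routes — the EM analogue on Boolean-encoded networks:
  support-minimal node sets whose exclusive activation is a fixed point that
  keeps the target on.  Case-study networks mix compounds and reactions as
  plain Boolean nodes, so this is the notion their printed EM decompositions
  actually use.

Reversible reactions are split into irreversible forward/backward halves
(backward named ``<name>__rev``) before any LP is built; the futile
forward+backward two-cycles this creates are excluded from EM output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .boolnet import BooleanNetwork, is_fixed_point
from .milp import LinearProgram
from .solve import INFEASIBLE, OPTIMAL, SolverConfig, SolverError, solve

__all__ = [
    "StoichiometricModel", "EMCandidate", "REV_SUFFIX",
    "parse_reactions_tsv", "parse_matrix_tsv",
    "steady_flux_feasible", "support_minimality_milp",
    "enumerate_ems_bruteforce", "boolean_activation_routes",
    "em_selectivity_check",
]

REV_SUFFIX = "__rev"
DEFAULT_BIG_M = 1000.0
DEFAULT_EPS_TOT = 1e-3
_FLUX_TOL = 1e-9
_BRUTEFORCE_MAX_REACTIONS = 15
_ROUTES_MAX_NODES = 20


@dataclass(frozen=True)
class StoichiometricModel:
    """Species × reaction matrix with reversibility flags.

    ``boundary`` species are exempt from steady-state balancing (classic
    external metabolites).
    """

    species: tuple[str, ...]
    reactions: tuple[str, ...]
    matrix: np.ndarray
    irreversible: tuple[bool, ...]
    boundary: frozenset[str] = frozenset()

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        if mat.shape != (len(self.species), len(self.reactions)):
            raise ValueError("matrix shape does not match species/reaction lists")
        if len(self.irreversible) != len(self.reactions):
            raise ValueError("one reversibility flag per reaction required")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        if len(set(self.reactions)) != len(self.reactions):
            raise ValueError("duplicate reaction names")
        if not self.boundary <= set(self.species):
            raise ValueError("boundary names must be species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def balanced_matrix(self) -> np.ndarray:
        keep = [i for i, s in enumerate(self.species) if s not in self.boundary]
        return self.matrix[keep, :]

    def split_reversible(self) -> "StoichiometricModel":
        """All-irreversible model; each reversible column gains a negated
        ``__rev`` twin appended after the original column order."""
        if all(self.irreversible):
            return self
        cols = [self.matrix[:, j] for j in range(self.n_reactions)]
        names = list(self.reactions)
        for j, irr in enumerate(self.irreversible):
            if not irr:
                names.append(self.reactions[j] + REV_SUFFIX)
                cols.append(-self.matrix[:, j])
        return StoichiometricModel(
            self.species, tuple(names), np.column_stack(cols),
            tuple(True for _ in names), self.boundary)


@dataclass(frozen=True)
class EMCandidate:
    """A support-minimal steady flux: active reactions plus a witness rate
    vector satisfying ``N v = 0`` on balanced species."""

    support: frozenset[str]
    flux: dict[str, float]
    is_em: bool


# ---------------------------------------------------------------------------
# plain-text formats

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z0-9_]+)\s*$")


def _parse_side(side: str, line: int) -> list[tuple[str, float]]:
    side = side.strip()
    if not side:
        return []
    out = []
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"line {line}: bad species term {term.strip()!r}")
        out.append((m.group(2), float(m.group(1) or 1.0)))
    return out


def _directives(text: str) -> tuple[set[str], set[str], list[tuple[int, str]]]:
    boundary: set[str] = set()
    reversible: set[str] = set()
    body: list[tuple[int, str]] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            payload = line.lstrip("#").strip()
            for key, sink in (("boundary:", boundary), ("reversible:", reversible)):
                if payload.lower().startswith(key):
                    sink.update(payload[len(key):].replace(",", " ").split())
            continue
        body.append((ln, raw.rstrip("\n")))
    return boundary, reversible, body


def parse_reactions_tsv(text: str) -> StoichiometricModel:
    """Reaction-list format: ``name<TAB>equation<TAB>irreversible-flag``.

    Equations read ``A + 2 B -> C`` (``<->`` marks a reversible reaction, as
    does flag 0; the flag column is optional and defaults to irreversible).
    ``# boundary: X Y`` directives exempt species from balancing.
    """
    boundary, _, body = _directives(text)
    if not body:
        raise ValueError("empty stoichiometric file")
    names: list[str] = []
    species: dict[str, int] = {}
    entries: list[tuple[list, list, bool]] = []
    for ln, line in body:
        fields = [f.strip() for f in line.split("\t") if f.strip()]
        if len(fields) < 2:
            raise ValueError(f"line {ln}: expected name<TAB>equation")
        name, eq = fields[0], fields[1]
        if name in names:
            raise ValueError(f"line {ln}: duplicate reaction {name!r}")
        reversible = "<->" in eq
        eq = eq.replace("<->", "->")
        if "->" not in eq:
            raise ValueError(f"line {ln}: equation needs '->'")
        lhs, rhs = eq.split("->", 1)
        if len(fields) >= 3:
            reversible = reversible or fields[2] == "0"
        subs, prods = _parse_side(lhs, ln), _parse_side(rhs, ln)
        for sp, _ in subs + prods:
            species.setdefault(sp, len(species))
        names.append(name)
        entries.append((subs, prods, not reversible))
    mat = np.zeros((len(species), len(names)))
    for j, (subs, prods, _) in enumerate(entries):
        for sp, coef in subs:
            mat[species[sp], j] -= coef
        for sp, coef in prods:
            mat[species[sp], j] += coef
    return StoichiometricModel(
        tuple(species), tuple(names), mat,
        tuple(irr for _, _, irr in entries), frozenset(boundary))


def parse_matrix_tsv(text: str) -> StoichiometricModel:
    """Dense matrix format: header row of reaction names, then one row per
    species (name first).  ``# boundary:`` / ``# reversible:`` directives as
    in the reaction-list format."""
    boundary, reversible, body = _directives(text)
    if len(body) < 2:
        raise ValueError("matrix file needs a header row and at least one species row")
    header = body[0][1].split("\t")
    reactions = [h.strip() for h in header if h.strip()]
    species, rows = [], []
    for ln, line in body[1:]:
        fields = line.split("\t")
        if len(fields) != len(reactions) + 1:
            raise ValueError(f"line {ln}: expected {len(reactions) + 1} columns")
        species.append(fields[0].strip())
        rows.append([float(f) for f in fields[1:]])
    return StoichiometricModel(
        tuple(species), tuple(reactions), np.array(rows),
        tuple(r not in reversible for r in reactions), frozenset(boundary))


# ---------------------------------------------------------------------------
# steady-state LP / MILP


def _expand_support(split: StoichiometricModel, original: StoichiometricModel,
                    support: Iterable[str]) -> frozenset[str]:
    """Map support names onto split columns.  A reversible *original* name
    activates both directions; split names (``name``/``name__rev``) activate
    exactly themselves."""
    cols = set(split.reactions)
    rev_originals = {r for r, irr in zip(original.reactions, original.irreversible)
                     if not irr}
    out: set[str] = set()
    for name in support:
        if name not in cols:
            raise ValueError(f"unknown reaction {name!r}")
        out.add(name)
        if name in rev_originals:
            out.add(name + REV_SUFFIX)
    return frozenset(out)


def steady_flux_feasible(model: StoichiometricModel, support: Iterable[str],
                         big_m: float = DEFAULT_BIG_M,
                         eps_tot: float = DEFAULT_EPS_TOT
                         ) -> tuple[bool, dict[str, float] | None]:
    """Does a nonzero steady flux confined to ``support`` exist?

    Feasibility certifies existence (``N v = 0`` on balanced species,
    ``0 ≤ v_j ≤ M`` inside S, ``v_j = 0`` outside, ``Σ v_j ≥ ε_tot``) but not
    minimality.  Returns the flux witness on success.
    """
    if big_m <= 0 or eps_tot <= 0:
        raise ValueError("big_m and eps_tot must be positive")
    split = model.split_reversible()
    if split.n_reactions == 0:
        raise ValueError("model has no reactions")
    cols = _expand_support(split, model, support)
    bounds = [(0.0, big_m if r in cols else 0.0) for r in split.reactions]
    n_bal = split.balanced_matrix().shape[0]
    res = linprog(
        c=np.zeros(split.n_reactions),
        A_eq=split.balanced_matrix() if n_bal else None,
        b_eq=np.zeros(n_bal) if n_bal else None,
        A_ub=-np.ones((1, split.n_reactions)),
        b_ub=np.array([-eps_tot]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": 1e-10},
    )
    if res.status == 0:
        witness = {r: float(v) for r, v in zip(split.reactions, res.x)
                   if v > _FLUX_TOL}
        return True, witness
    if res.status == 2:
        return False, None
    raise SolverError(f"linprog status {res.status}: {res.message}")


def support_minimality_milp(model: StoichiometricModel, support: Iterable[str],
                            big_m: float = DEFAULT_BIG_M,
                            eps_tot: float = DEFAULT_EPS_TOT,
                            config: SolverConfig | None = None) -> bool:
    """True iff ``min Σ y_j`` over steady fluxes confined to S equals |S|.

    An optimum below |S| exhibits a strictly smaller-support steady flux
    inside S, so S is not an elementary mode.  Requires
    :func:`steady_flux_feasible` to hold for S; an infeasible inner MILP
    signals that precondition was violated.
    """
    if big_m <= 0 or eps_tot <= 0:
        raise ValueError("big_m and eps_tot must be positive")
    split = model.split_reversible()
    cols = sorted(_expand_support(split, model, support))
    lp = LinearProgram()
    vvars = {r: lp.add_continuous(f"v.{r}", 0.0, big_m if r in cols else 0.0)
             for r in split.reactions}
    yvars = {r: lp.add_binary(f"y.{r}") for r in cols}
    bal = split.balanced_matrix()
    for i in range(bal.shape[0]):
        terms = [(vvars[r], bal[i, j]) for j, r in enumerate(split.reactions)
                 if bal[i, j] != 0.0]
        if terms:
            lp.add_constraint(terms, "=", 0.0)
    for r in cols:
        lp.add_constraint([(vvars[r], 1.0), (yvars[r], -big_m)], "<=", 0.0)
    lp.add_constraint([(v, 1.0) for v in vvars.values()], ">=", eps_tot)
    lp.set_objective([(y, 1.0) for y in yvars.values()], "min")
    res = solve(lp, config)
    if res.status == INFEASIBLE:
        raise ValueError("support admits no nonzero steady flux; "
                         "check steady_flux_feasible first")
    if res.status != OPTIMAL:
        raise SolverError("support-minimality MILP did not reach optimality")
    return int(round(res.objective)) == len(cols)


def _is_futile_pair(support: frozenset[str]) -> bool:
    if len(support) != 2:
        return False
    a, b = sorted(support)
    return b == a + REV_SUFFIX


def enumerate_ems_bruteforce(model: StoichiometricModel,
                             max_support: int | None = None,
                             big_m: float = DEFAULT_BIG_M,
                             eps_tot: float = DEFAULT_EPS_TOT
                             ) -> list[EMCandidate]:
    """All elementary modes by exhaustive subset feasibility — the oracle.

    Scans supports in order of increasing size, pruning supersets of anything
    already feasible, so each emitted support is support-minimal by
    construction.  Futile forward/backward pairs of a split reversible
    reaction are pruned but not reported.  Guarded to ≤ 15 reactions
    (after splitting); sorted by (size, lexicographic support).
    """
    split = model.split_reversible()
    r = split.n_reactions
    if r == 0:
        raise ValueError("model has no reactions")
    if r > _BRUTEFORCE_MAX_REACTIONS:
        raise ValueError(
            f"{r} reactions exceed the brute-force budget "
            f"({_BRUTEFORCE_MAX_REACTIONS}); this enumerator is an oracle, "
            "not a scalable algorithm")
    minimal_feasible: list[frozenset[str]] = []
    ems: list[EMCandidate] = []
    for size in range(1, (max_support or r) + 1):
        for comb in combinations(split.reactions, size):
            s = frozenset(comb)
            if any(p <= s for p in minimal_feasible):
                continue
            ok, witness = steady_flux_feasible(split, s, big_m, eps_tot)
            if not ok:
                continue
            minimal_feasible.append(s)
            if _is_futile_pair(s):
                continue
            ems.append(EMCandidate(support=s, flux=witness, is_em=True))
    ems.sort(key=lambda e: (len(e.support), sorted(e.support)))
    return ems


# ---------------------------------------------------------------------------
# Boolean activation routes


def boolean_activation_routes(net: BooleanNetwork, target: str,
                              max_size: int | None = None) -> list[frozenset[str]]:
    """Support-minimal node sets T ∋ target whose exclusive activation is a
    fixed point: nodes in T at 1, all other nodes (inputs included) at 0.

    This is the elementary-mode analogue on a Boolean-encoded network; the
    returned list is an antichain under set inclusion, sorted by
    (size, lexicographic).  Guarded to ≤ 20 nodes.
    """
    if target not in net.nodes:
        raise ValueError(f"target {target!r} not in network")
    if len(net.nodes) > _ROUTES_MAX_NODES:
        raise ValueError(f"route enumeration guarded to {_ROUTES_MAX_NODES} nodes")
    others = [n for n in net.nodes if n != target]
    cap = (max_size - 1) if max_size is not None else len(others)
    routes: list[frozenset[str]] = []
    for size in range(0, cap + 1):
        for comb in combinations(others, size):
            t_set = frozenset(comb) | {target}
            if any(r <= t_set for r in routes):
                continue
            state = {n: 1 if n in t_set else 0 for n in net.nodes}
            if is_fixed_point(net, state):
                routes.append(t_set)
    return sorted(routes, key=lambda s: (len(s), sorted(s)))


def em_selectivity_check(support: Iterable[str],
                         routes_a: Sequence[frozenset[str]],
                         routes_b: Sequence[frozenset[str]]) -> bool:
    """Selectivity in the elementary-mode sense: S is a mode of network A and
    not a mode of network B (set equality on supports; ∅ is never a mode)."""
    s = frozenset(support)
    if not s:
        return False
    return s in set(routes_a) and s not in set(routes_b)
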