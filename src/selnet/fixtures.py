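"""Case-study reconstruction and generators for tests and benchmarks.

``make_mkmn_pair`` loads the committed two-network metabolic-circuit
reconstruction (13 shared nodes; variant A funnels every activation route for
C9 through the C6/C7/r3 branch, variant B keeps three independent routes).
The reconstruction is data — plain rule files under ``selnet/data`` — so a
different topology can be substituted without touching code.

``random_pair`` draws structurally similar acyclic network pairs for
property-based testing against the brute-force oracle; ``random_stoich``
draws small stoichiometric models for the elementary-mode oracle suite.
Both are fully reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .boolnet import BooleanNetwork, NetworkPair, parse_rules
from .em import StoichiometricModel, parse_reactions_tsv

__all__ = [
    "PairGenConfig", "fixture_text", "fixture_names",
    "make_mkmn_pair", "make_toy_stoich", "random_pair", "random_stoich",
]

_TOY_KINDS = ("chain", "parallel", "cycle")
_FIXTURE_FILES = ("mkmn_a.rules", "mkmn_b.rules",
                  "chain.tsv", "parallel.tsv", "cycle.tsv")


def fixture_names() -> tuple[str, ...]:
    return _FIXTURE_FILES


def fixture_text(name: str) -> str:
    if name not in _FIXTURE_FILES:
        raise ValueError(f"unknown fixture {name!r}")
    return (resources.files("selnet") / "data" / name).read_text()


def make_mkmn_pair() -> NetworkPair:
    """The committed MKMN case-study reconstruction (A pathological, B healthy)."""
    return NetworkPair(parse_rules(fixture_text("mkmn_a.rules")),
                       parse_rules(fixture_text("mkmn_b.rules")))


def make_toy_stoich(kind: str) -> StoichiometricModel:
    """Toy stoichiometric models with analytically known elementary modes:
    ``chain`` (1 EM), ``parallel`` (2 EMs), ``cycle`` (internal cycle +
    through-path, 2 EMs)."""
    if kind not in _TOY_KINDS:
        raise ValueError(f"kind must be one of {_TOY_KINDS}")
    return parse_reactions_tsv(fixture_text(f"{kind}.tsv"))


@dataclass(frozen=True)
class PairGenConfig:
    """Settings for random structurally-similar pairs.

    ``edge_density`` tunes the expected in-degree of non-input nodes (1–3
    parents); ``n_edge_diffs`` is the number of single-edge differences
    applied to derive network B from network A (0 gives identical networks).
    """

    n_nodes: int = 8
    n_inputs: int = 2
    edge_density: float = 0.35
    n_edge_diffs: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_nodes <= self.n_inputs:
            raise ValueError("need at least one input and one regulated node")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        if self.n_edge_diffs < 0:
            raise ValueError("n_edge_diffs must be non-negative")


def _spec_text(names, n_inputs, specs) -> str:
    lines = [f"input {n} = 1" for n in names[:n_inputs]]
    for node in names[n_inputs:]:
        kind, lits = specs[node]
        rendered = [("!" + p) if neg else p for p, neg in lits]
        op = " & " if kind == "AND" else " | "
        lines.append(f"{node} = {op.join(rendered)}")
    return "\n".join(lines) + "\n"


def random_pair(cfg: PairGenConfig) -> NetworkPair:
    """A seeded pair of acyclic networks differing in ``n_edge_diffs`` edges.

    Nodes are topologically ordered at generation time (parents always
    precede children), so every clamped configuration has a unique fixed
    point — the regime where the brute-force oracle is exact.
    """
    rng = np.random.default_rng(cfg.seed)
    names = [f"v{i}" for i in range(cfg.n_nodes)]
    specs_a: dict[str, tuple[str, list[tuple[str, bool]]]] = {}
    for i in range(cfg.n_inputs, cfg.n_nodes):
        pool = names[:i]
        kmax = min(len(pool), 3)
        k = 1 + rng.binomial(kmax - 1, cfg.edge_density)
        parents = [str(p) for p in rng.choice(pool, size=k, replace=False)]
        kind = "AND" if rng.random() < 0.5 else "OR"
        lits = [(p, bool(rng.random() < 0.25)) for p in parents]
        specs_a[names[i]] = (kind, lits)

    specs_b = {n: (kind, list(lits)) for n, (kind, lits) in specs_a.items()}
    regulated = names[cfg.n_inputs:]
    touched: set[tuple[str, str]] = set()
    for _ in range(cfg.n_edge_diffs):
        for _attempt in range(500):
            node = str(rng.choice(regulated))
            kind, lits = specs_b[node]
            pool = names[:names.index(node)]
            present = {p for p, _ in lits}
            addable = [p for p in pool
                       if p not in present and (node, p) not in touched]
            removable = [p for p, _ in lits if (node, p) not in touched]
            if rng.random() < 0.5 and addable:
                p = str(rng.choice(addable))
                lits.append((p, bool(rng.random() < 0.25)))
                touched.add((node, p))
                break
            if len(lits) >= 2 and removable:
                p = str(rng.choice(removable))
                lits[:] = [(q, neg) for q, neg in lits if q != p]
                touched.add((node, p))
                break
        else:
            raise ValueError("could not realize the requested edge differences")
    net_a = parse_rules(_spec_text(names, cfg.n_inputs, specs_a))
    net_b = parse_rules(_spec_text(names, cfg.n_inputs, specs_b))
    return NetworkPair(net_a, net_b)


def random_stoich(n_reactions: int = 8, n_species: int = 6,
                  seed: int = 0) -> StoichiometricModel:
    """A seeded small irreversible model: mostly source-to-sink conversions
    (first and last species are boundary) with occasional backward edges and
    two-substrate reactions, so routes, branches and cycles all occur."""
    if n_reactions < 1 or n_species < 3:
        raise ValueError("need at least one reaction and three species")
    rng = np.random.default_rng(seed)
    species = [f"S{i}" for i in range(n_species)]
    mat = np.zeros((n_species, n_reactions))
    for j in range(n_reactions):
        if rng.random() < 0.8:  # forward conversion
            s = int(rng.integers(0, n_species - 1))
            p = int(rng.integers(s + 1, n_species))
        else:  # backward edge, may close a cycle
            p = int(rng.integers(0, n_species - 1))
            s = int(rng.integers(p + 1, n_species))
        mat[s, j] -= 1.0
        mat[p, j] += 1.0
        if rng.random() < 0.2:  # second substrate
            extra = int(rng.integers(0, n_species))
            if extra not in (s, p):
                mat[extra, j] -= 1.0
    return StoichiometricModel(
        tuple(species), tuple(f"r{j + 1}" for j in range(n_reactions)), mat,
        tuple(True for _ in range(n_reactions)),
        frozenset({species[0], species[-1]}))
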