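"""Chemical reaction network theory: deficiency and multistationarity screening.

The deficiency of a mass-action network is δ = n − l − s, where n is the
number of distinct complexes, l the number of linkage classes (connected
components of the complex graph) and s the rank of the stoichiometric
subspace.  Deficiency-zero weakly reversible networks cannot admit
multiple positive steady states in any stoichiometric compatibility
class, so such networks are reported as excluded without search.  For all
other networks this module pairs the structural numbers with an explicit
numerical multistart search over random rate constants: finding two
coexisting stable states is a constructive witness of multistationarity,
while finding none is reported as exactly that — a search outcome, never
a proof of impossibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .network import ReactionNetwork
from .parameters import ParameterSet
from .response import is_stable, refine_root

Complex = Tuple[Tuple[str, int], ...]


def _complex_of(multiset, clamped) -> Complex:
    items = tuple(sorted((s, c) for s, c in multiset.items() if s not in clamped))
    return items  # () is the empty complex (all members clamped)


def complex_graph(network: ReactionNetwork,
                  drop_clamped: bool = True) -> nx.MultiDiGraph:
    """Directed graph on complexes; one edge per reaction."""
    clamped = set(network.clamped) if drop_clamped else set()
    g = nx.MultiDiGraph()
    for rxn in network.reactions:
        a = _complex_of(rxn.reactants, clamped)
        b = _complex_of(rxn.products, clamped)
        g.add_node(a)
        g.add_node(b)
        g.add_edge(a, b, rate=rxn.rate)
    return g


VERDICTS = ("multiple_states_found", "none_found_in_search",
            "excluded_by_deficiency_zero", "not_searched")


@dataclass
class DeficiencyReport:
    """Structural CRNT numbers plus the multistationarity verdict."""

    n: int                       # distinct complexes
    l: int                       # linkage classes
    s: int                       # rank of the stoichiometric subspace
    deficiency: int
    weakly_reversible: bool
    clamped_removed: Tuple[str, ...]
    multistationarity_verdict: str = "not_searched"
    witnesses: List[dict] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        return {
            "n_complexes": self.n,
            "n_linkage_classes": self.l,
            "stoichiometric_rank": self.s,
            "deficiency": self.deficiency,
            "weakly_reversible": self.weakly_reversible,
            "clamped_species_removed": list(self.clamped_removed),
            "multistationarity_verdict": self.multistationarity_verdict,
            "witnesses": self.witnesses,
        }


def network_deficiency(network: ReactionNetwork,
                       drop_clamped: bool = True) -> DeficiencyReport:
    """Compute n, l, s and δ = n − l − s for a mass-action network.

    Clamped species (ATP) are removed before complexes are formed by
    default; the report records which were removed.
    """
    g = complex_graph(network, drop_clamped=drop_clamped)
    n = g.number_of_nodes()
    undirected = nx.Graph(g)
    components = list(nx.connected_components(undirected))
    l = len(components)
    s = int(np.linalg.matrix_rank(network.stoichiometry))
    delta = n - l - s
    if delta < 0:
        raise RuntimeError(f"negative deficiency {delta}: inconsistent network")
    sccs = list(nx.strongly_connected_components(g))
    weakly_reversible = len(sccs) == l
    report = DeficiencyReport(
        n=n, l=l, s=s, deficiency=delta,
        weakly_reversible=weakly_reversible,
        clamped_removed=tuple(network.clamped) if drop_clamped else (),
    )
    if delta == 0 and weakly_reversible:
        report.multistationarity_verdict = "excluded_by_deficiency_zero"
    return report


# ----------------------------------------------------------------------
# numerical multistationarity search
# ----------------------------------------------------------------------
def default_sampler(
    network: ReactionNetwork,
    rate_bounds: Tuple[float, float] = (1e-3, 1e3),
    total_bounds: Tuple[float, float] = (1.0, 300.0),
) -> Callable[[np.ndarray], ParameterSet]:
    """Log-uniform sampler over every rate label and conserved total.

    Returns a callable mapping an RNG to a ParameterSet in which all rate
    labels of the network (and the totals its initial state needs)
    resolve.
    """
    labels = sorted({r.rate for r in network.reactions})
    totals = sorted({
        total for pair in ReactionNetwork._PHOSPHO_PAIRS
        for name, total in ((pair[0], pair[2]), (pair[1], pair[2]))
        if name in network.dynamic_species
    } | {
        total for name, total in ReactionNetwork._FREE_SPECIES
        if name in network.dynamic_species
    })

    def sample(rng: np.random.Generator) -> ParameterSet:
        values: Dict[str, float] = {}
        for lab in labels:
            values[lab] = float(np.exp(rng.uniform(*np.log(rate_bounds))))
        for lab in totals:
            values[lab] = float(np.exp(rng.uniform(*np.log(total_bounds))))
        return ParameterSet().with_(**values)

    return sample


def random_states_in_class(
    network: ReactionNetwork,
    anchor: np.ndarray,
    n: int,
    rng: np.random.Generator,
    mix_steps: int = 5,
) -> np.ndarray:
    """Random nonnegative states sharing the conserved totals of ``anchor``.

    Hit-and-run in the stoichiometric compatibility class: repeatedly move
    along random directions in range(N) within the nonnegative orthant, so
    conservation holds exactly by construction.  Directions whose feasible
    interval degenerates (the walker sits on a face) are re-drawn.
    """
    N = network.stoichiometry
    out = np.empty((n, len(anchor)))
    y = np.asarray(anchor, dtype=float).copy()
    for i in range(n):
        for _ in range(mix_steps):
            for _try in range(20):
                d = N @ rng.standard_normal(N.shape[1])
                nd = np.linalg.norm(d)
                if nd < 1e-12:
                    continue
                d /= nd
                # max step keeping y + a*d >= 0 in both directions
                with np.errstate(divide="ignore", invalid="ignore"):
                    pos = np.where(d < -1e-12, -y / d, np.inf)
                    neg = np.where(d > 1e-12, y / d, np.inf)
                a_hi, a_lo = float(np.min(pos)), -float(np.min(neg))
                if not np.isfinite(a_hi):
                    a_hi = np.linalg.norm(y) + 1.0
                if not np.isfinite(a_lo):
                    a_lo = -(np.linalg.norm(y) + 1.0)
                if a_hi - a_lo > 1e-9 * (1.0 + np.linalg.norm(y)):
                    # stay off the faces so later directions remain feasible
                    y = y + rng.uniform(0.05, 0.95) * (a_hi - a_lo) * d + a_lo * d
                    y = np.maximum(y, 0.0)
                    break
        out[i] = y
    return out


@dataclass
class SearchResult:
    verdict: str
    witnesses: List[dict]
    n_draws: int
    report: Optional[DeficiencyReport] = None


def _distinct_stable_states(network, params, starts, rhs_tol=1e-10):
    roots: List[np.ndarray] = []
    seen: List[np.ndarray] = []
    for y0 in starts:
        root = refine_root(network, params, y0, fast=True)
        if root is None:
            continue
        if any(np.max(np.abs(root - r)) < 1e-5 * (1 + np.max(np.abs(r))) for r in seen):
            continue
        seen.append(root)
        if np.linalg.norm(network.rhs(root, params)) > rhs_tol * (1 + np.linalg.norm(root)):
            continue
        if not is_stable(network, params, root):
            continue
        roots.append(root)
    return roots


def multistationarity_search(
    network: ReactionNetwork,
    param_sampler: Optional[Callable[[np.random.Generator], ParameterSet]] = None,
    n_draws: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
    stop_at_first: bool = True,
) -> SearchResult:
    """Search random mass-action parameterizations for coexisting stable states.

    For each parameter draw, steady states are solved from ``n_starts``
    random initial conditions inside one stoichiometric compatibility
    class; two distinct stable validated states constitute a witness.  A
    deficiency-zero weakly reversible network is excluded structurally and
    not searched.  An empty witness list means none were found *in this
    search* — it is not a proof of impossibility.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    report = network_deficiency(network)
    if report.multistationarity_verdict == "excluded_by_deficiency_zero":
        return SearchResult("excluded_by_deficiency_zero", [], 0, report)
    if param_sampler is None:
        param_sampler = default_sampler(network)
    rng = np.random.default_rng(seed)
    L = network.conservation_laws()
    witnesses: List[dict] = []
    for draw in range(int(n_draws)):
        params = param_sampler(rng)
        lo = network.initial_state(params, phospho=False)
        hi = network.initial_state(params, phospho=True)
        mid = 0.5 * (lo + hi)
        n_random = max(n_starts - 2, 0)
        starts = [lo, hi]
        if n_random:
            starts.append(random_states_in_class(network, mid, n_random, rng))
        starts = np.vstack([np.atleast_2d(s) for s in starts])
        roots = _distinct_stable_states(network, params, starts)
        if len(roots) >= 2:
            t0 = L @ roots[0]
            valid = all(
                np.max(np.abs(L @ r - t0)) <= 1e-8 * (1 + np.max(np.abs(t0)))
                for r in roots
            )
            if valid:
                witnesses.append({
                    "draw": draw,
                    "parameters": params.to_dict(),
                    "states": [r.tolist() for r in roots[:2]],
                    "species": list(network.dynamic_species),
                })
                if stop_at_first:
                    break
    verdict = "multiple_states_found" if witnesses else "none_found_in_search"
    report.multistationarity_verdict = verdict
    report.witnesses = witnesses
    return SearchResult(verdict, witnesses, int(n_draws), report)
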