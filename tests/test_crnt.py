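import numpy as np
import pytest

from splitkinase import (
    ParameterSet,
    build_architecture,
    multistationarity_search,
    network_deficiency,
)
from splitkinase.crnt import _distinct_stable_states, default_sampler
from splitkinase.network import Reaction, ReactionNetwork


def independent_deficiency(network):
    """Second, independent enumeration of (n, l, delta) for cross-checking.

    Builds the complex set and linkage classes with plain dict/set
    union-find instead of networkx, and the rank from sympy's exact
    arithmetic instead of numpy's SVD.
    """
    import sympy

    clamped = set(network.clamped)
    cplx = []

    def key(ms):
        return tuple(sorted((s, c) for s, c in ms.items() if s not in clamped))

    edges = []
    for rxn in network.reactions:
        a, b = key(rxn.reactants), key(rxn.products)
        for c in (a, b):
            if c not in cplx:
                cplx.append(c)
        edges.append((cplx.index(a), cplx.index(b)))
    parent = list(range(len(cplx)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in edges:
        parent[find(a)] = find(b)
    n = len(cplx)
    l = len({find(i) for i in range(n)})
    s = sympy.Matrix(network.stoichiometry.astype(int)).rank()
    return n, l, n - l - s


def test_reversible_isomerization_is_deficiency_zero():
    net = ReactionNetwork(("A", "B"), [Reaction({"A": 1}, {"B": 1}, "k1"),
                                       Reaction({"B": 1}, {"A": 1}, "k2")])
    rep = network_deficiency(net)
    assert (rep.n, rep.l, rep.s, rep.deficiency) == (2, 1, 1, 0)
    assert rep.weakly_reversible
    assert rep.multistationarity_verdict == "excluded_by_deficiency_zero"


def test_three_cycle_by_hand_enumeration():
    # A+B -> C -> D -> A+B: complexes {A+B, C, D}, one linkage class, rank 2
    net = ReactionNetwork(
        ("A", "B", "C", "D"),
        [Reaction({"A": 1, "B": 1}, {"C": 1}, "k1"),
         Reaction({"C": 1}, {"D": 1}, "k2"),
         Reaction({"D": 1}, {"A": 1, "B": 1}, "k3")],
    )
    rep = network_deficiency(net)
    assert (rep.n, rep.l, rep.s, rep.deficiency) == (3, 1, 2, 0)
    assert rep.weakly_reversible  # the cycle is strongly connected


def test_basic_network_deficiency_regression(basic_network):
    rep = network_deficiency(basic_network)
    n, l, delta = independent_deficiency(basic_network)
    assert (rep.n, rep.l) == (n, l)
    assert rep.deficiency == delta
    # frozen after independent enumeration: 10 complexes (ATP removed),
    # 3 linkage classes, rank 5 => deficiency 2
    assert (rep.n, rep.l, rep.s, rep.deficiency) == (10, 3, 5, 2)
    assert "ATP" in rep.clamped_removed
    assert not rep.weakly_reversible


@pytest.mark.parametrize("arch,expected_delta", [
    ("bifunctional_nonsplit", 2),
    ("monofunctional_plus_Z", 2),
    ("monofunctional_split", 1),
])
def test_architecture_deficiencies_cross_checked(arch, expected_delta):
    net, _ = build_architecture(arch)
    rep = network_deficiency(net)
    n, l, delta = independent_deficiency(net)
    assert (rep.n, rep.l, rep.deficiency) == (n, l, delta)
    assert rep.deficiency == expected_delta


def test_deficiency_additive_over_disjoint_union(rng):
    """delta(N1 ⊔ N2) = delta(N1) + delta(N2) for renamed random pairs."""
    def random_net(tag, n_species, n_rxn, rig):
        species = [f"{tag}X{i}" for i in range(n_species)]
        rxns = []
        for j in range(n_rxn):
            a, b = rig.choice(n_species, 2, replace=False)
            rxns.append(Reaction({species[a]: 1}, {species[b]: 1}, f"{tag}k{j}"))
        return species, rxns

    for trial in range(5):
        rig = np.random.default_rng(100 + trial)
        s1, r1 = random_net("L", 4, 5, rig)
        s2, r2 = random_net("R", 3, 4, rig)
        d1 = network_deficiency(ReactionNetwork(s1, r1)).deficiency
        d2 = network_deficiency(ReactionNetwork(s2, r2)).deficiency
        d12 = network_deficiency(ReactionNetwork(s1 + s2, list(r1) + list(r2))).deficiency
        assert d12 == d1 + d2


def test_basic_model_search_finds_validated_witness(basic_network):
    """At literature rates with the signal scanned, two stable states coexist."""
    def pinned(rng):
        return ParameterSet().with_(k5=float(rng.uniform(0.0, 10.0)))

    result = multistationarity_search(basic_network, param_sampler=pinned,
                                      n_draws=40, seed=1, n_starts=12)
    assert result.verdict == "multiple_states_found"
    w = result.witnesses[0]
    params = ParameterSet().with_(**{k: v for k, v in w["parameters"].items()
                                     if k not in ("extras",)})
    L = basic_network.conservation_laws()
    states = [np.array(s) for s in w["states"]]
    from splitkinase.response import is_stable

    t0 = L @ states[0]
    for s in states:
        r = basic_network.rhs(s, params)
        assert np.linalg.norm(r) < 1e-10 * (1 + np.linalg.norm(s))
        assert is_stable(basic_network, params, s)
        assert np.max(np.abs(L @ s - t0)) < 1e-8 * (1 + np.max(np.abs(t0)))
    assert np.max(np.abs(states[0] - states[1])) > 1.0


def test_monomolecular_cycle_has_unique_state_per_draw(rng):
    """A <-> B is linear: every random parameterization yields one steady state."""
    net = ReactionNetwork(("A", "B"), [Reaction({"A": 1}, {"B": 1}, "kf"),
                                       Reaction({"B": 1}, {"A": 1}, "kr")])
    sampler = default_sampler(net)
    for _ in range(25):
        params = sampler(rng)
        anchor = np.array([rng.uniform(1.0, 50.0), rng.uniform(1.0, 50.0)])
        from splitkinase.crnt import random_states_in_class

        starts = random_states_in_class(net, anchor, 8, rng)
        roots = _distinct_stable_states(net, params, starts)
        assert len(roots) == 1


def test_search_input_validation(basic_network):
    with pytest.raises(ValueError):
        multistationarity_search(basic_network, n_draws=0)
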