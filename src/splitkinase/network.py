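"""Mass-action reaction networks and time-course simulation.

The split kinase of *R. sphaeroides* is a bipartite histidine kinase:
CheA4 carries the ATP-binding/catalytic (P4) domain and CheA3 the
phosphorylatable (P1) domain, so autophosphorylation requires transient
formation of a CheA3:CheA4 complex.  Phospho-CheA3 then donates its
phosphoryl group to the response regulator CheY6, while *free* CheA3
additionally acts as the phosphatase for CheY6-P.  The basic model is the
eleven-reaction mass-action scheme over eight dynamic species with ATP
clamped; three conserved moieties (total CheA3, CheA4, CheY6) follow from
the stoichiometry.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

from .parameters import ParameterSet

#: species order of the basic model
BASIC_SPECIES = ("A3", "A4", "A3A4", "A3A4T", "A3p", "Y6", "Y6p", "A3Y6p")

#: integration tolerances — rates span ~5 orders of magnitude, so the
#: system is stiff and integrated with LSODA at tight tolerances.
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    ``reactants`` / ``products`` map species name to stoichiometric
    coefficient; ``rate`` is the label of the rate constant, resolved
    against a :class:`~splitkinase.parameters.ParameterSet` at simulation
    time.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate: str

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))


class ReactionNetwork:
    """An ordered list of species plus mass-action reactions.

    ``clamped`` species (here: ATP) enter rate laws at a fixed
    concentration but are excluded from the dynamic state vector and from
    the stoichiometric matrix.
    """

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        clamped: Optional[Mapping[str, str]] = None,
        name: str = "network",
    ):
        self.species: Tuple[str, ...] = tuple(species)
        self.reactions: Tuple[Reaction, ...] = tuple(reactions)
        # clamped maps species name -> parameter label holding its level
        self.clamped: Dict[str, str] = dict(clamped or {})
        self.name = name
        dyn = [s for s in self.species if s not in self.clamped]
        self.dynamic_species: Tuple[str, ...] = tuple(dyn)
        self._index = {s: i for i, s in enumerate(dyn)}
        for rxn in self.reactions:
            for s in list(rxn.reactants) + list(rxn.products):
                if s not in self.species and s not in self.clamped:
                    raise ValueError(f"reaction references unknown species {s!r}")
        self._build_matrices()

    # ------------------------------------------------------------------
    def _build_matrices(self) -> None:
        ns, nr = len(self.dynamic_species), len(self.reactions)
        N = np.zeros((ns, nr))        # stoichiometric matrix (dynamic only)
        E = np.zeros((ns, nr))        # reactant-order exponents
        for j, rxn in enumerate(self.reactions):
            for s, c in rxn.reactants.items():
                if s in self._index:
                    N[self._index[s], j] -= c
                    E[self._index[s], j] += c
            for s, c in rxn.products.items():
                if s in self._index:
                    N[self._index[s], j] += c
        self.stoichiometry: np.ndarray = N
        self._exponents = E

    def n_species(self) -> int:
        return len(self.dynamic_species)

    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        return self._index[name]

    # ------------------------------------------------------------------
    def rate_vector(self, params: ParameterSet) -> np.ndarray:
        """Resolve every reaction's rate label, folding in clamped species.

        A clamped reactant (ATP) multiplies the effective rate constant by
        its fixed concentration.
        """
        k = np.empty(self.n_reactions())
        for j, rxn in enumerate(self.reactions):
            kj = params[rxn.rate]
            for s, c in rxn.reactants.items():
                if s in self.clamped:
                    kj *= params[self.clamped[s]] ** c
            k[j] = kj
        return k

    def fluxes(self, state: np.ndarray, k: np.ndarray) -> np.ndarray:
        """Mass-action flux of every reaction at ``state``."""
        y = np.maximum(np.asarray(state, dtype=float), 0.0)
        ex = self._exponents
        # prod_i y_i^{e_ij}; exponent 0 contributes nothing even at y=0
        monomial = np.prod(
            np.where(ex > 0, y[:, None] ** ex, 1.0), axis=0
        )
        return k * monomial

    def rhs(self, state: np.ndarray, params: ParameterSet) -> np.ndarray:
        """Time derivative of the dynamic state under mass action."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.n_species(),):
            raise ValueError(
                f"state has shape {state.shape}, expected ({self.n_species()},)"
            )
        k = self.rate_vector(params)
        return self.stoichiometry @ self.fluxes(state, k)

    def _bimolecular_index(self) -> Optional[Tuple[np.ndarray, np.ndarray]]:
        """Per-reaction reactant index pair for networks of order <= 2.

        Index ``n_species`` points at a padded constant 1.0, so a
        zeroth/first-order reaction simply multiplies by 1.
        """
        if hasattr(self, "_bi_cache"):
            return self._bi_cache
        E = self._exponents
        if np.any(E > 2) or np.any(E.sum(axis=0) > 2):
            self._bi_cache = None
            return None
        ns = self.n_species()
        i1 = np.full(self.n_reactions(), ns, dtype=int)
        i2 = np.full(self.n_reactions(), ns, dtype=int)
        for j in range(self.n_reactions()):
            idx = np.flatnonzero(E[:, j])
            slots = []
            for i in idx:
                slots.extend([i] * int(E[i, j]))
            if len(slots) >= 1:
                i1[j] = slots[0]
            if len(slots) == 2:
                i2[j] = slots[1]
        self._bi_cache = (i1, i2)
        return self._bi_cache

    def rhs_function(self, params: ParameterSet) -> Callable[[float, np.ndarray], np.ndarray]:
        """Compiled ``f(t, y)`` for the integrator (rates frozen)."""
        k = self.rate_vector(params)
        N = self.stoichiometry
        bi = self._bimolecular_index()
        if bi is not None:
            i1, i2 = bi
            ns = self.n_species()
            yc = np.ones(ns + 1)   # slot ns stays 1.0 (zeroth/first order pad)
            vbuf = np.empty(len(k))

            def f(t: float, y: np.ndarray) -> np.ndarray:
                np.maximum(y, 0.0, out=yc[:ns])
                np.multiply(k, yc[i1], out=vbuf)
                np.multiply(vbuf, yc[i2], out=vbuf)
                return N @ vbuf

            return f

        def f(t: float, y: np.ndarray) -> np.ndarray:
            return N @ self.fluxes(y, k)

        return f

    def jacobian_function(self, params: ParameterSet) -> Optional[
        Callable[[float, np.ndarray], np.ndarray]
    ]:
        """Analytic ODE Jacobian ``J(t, y)`` for order <= 2 networks.

        Returns None when a reaction exceeds second order (none of the
        built-in networks do); integrators then fall back to finite
        differences.
        """
        bi = self._bimolecular_index()
        if bi is None:
            return None
        k = self.rate_vector(params)
        N = self.stoichiometry
        i1, i2 = bi
        ns, nr = self.n_species(), self.n_reactions()
        rows = np.arange(nr)

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            yc = np.append(np.maximum(y, 0.0), 1.0)
            dv = np.zeros((nr, ns + 1))
            np.add.at(dv, (rows, i1), k * yc[i2])
            np.add.at(dv, (rows, i2), k * yc[i1])
            return N @ dv[:, :ns]

        return jac

    # ------------------------------------------------------------------
    def conservation_laws(self, tol: float = 1e-10) -> np.ndarray:
        """Basis of the left null space of the stoichiometric matrix.

        Rows are conserved linear combinations of dynamic species (for the
        basic model: total CheA3, CheA4 and CheY6).  Cached: the network
        is immutable after construction.
        """
        if not hasattr(self, "_cons_cache"):
            ns = null_space(self.stoichiometry.T, rcond=tol)
            self._cons_cache = ns.T  # each row is a conservation vector
        return self._cons_cache

    def conserved_totals(self, state: np.ndarray) -> np.ndarray:
        return self.conservation_laws() @ np.asarray(state, dtype=float)

    # ------------------------------------------------------------------
    #: (unphosphorylated form, phosphorylated form, total label) pairs and
    #: monomeric species recognized by initial_state
    _PHOSPHO_PAIRS = (
        ("A3", "A3p", "A3_tot"), ("Y6", "Y6p", "Y6_tot"),
        ("A2", "A2p", "A2_tot"), ("H", "Hp", "H_tot"), ("R", "Rp", "R_tot"),
    )
    _FREE_SPECIES = (("A4", "A4_tot"), ("Z", "Z_tot"))

    def initial_state(self, params: ParameterSet, phospho: bool = False) -> np.ndarray:
        """Conservation-consistent initial condition.

        All protein is free and unphosphorylated by default; with
        ``phospho=True`` the phosphorylatable proteins start fully
        phosphorylated, which seeds the upper branch in bistable regimes.
        """
        y = np.zeros(self.n_species())
        for unphos, phos, total in self._PHOSPHO_PAIRS:
            name = phos if phospho else unphos
            if name in self._index:
                y[self._index[name]] = params[total]
        for name, total in self._FREE_SPECIES:
            if name in self._index:
                y[self._index[name]] = params[total]
        return y

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ReactionNetwork {self.name!r}: {self.n_species()} species, "
            f"{self.n_reactions()} reactions>"
        )


# ----------------------------------------------------------------------
def build_basic_network(params: Optional[ParameterSet] = None) -> ReactionNetwork:
    """The eleven-reaction basic split-kinase network.

    R1/R2   A3 + A4 <-> A3A4                 (k1, k2)
    R3/R4   A3A4 + ATP <-> A3A4T             (k3, k4; ATP clamped)
    R5      A3A4T -> A3p + A4                (k5, the signal)
    R6/R7   A3p + Y6 <-> A3 + Y6p            (k6, k7)
    R8      Y6p -> Y6                        (k8)
    R9/R10  A3 + Y6p <-> A3Y6p               (k9, k10)
    R11     A3Y6p -> A3 + Y6                 (k11)

    ADP and Pi are not tracked.  ``params`` is only validated here; rates
    are resolved at simulation time so the same network serves any
    parameter set.
    """
    if params is not None and not isinstance(params, ParameterSet):
        raise TypeError("params must be a ParameterSet")
    reactions = [
        Reaction({"A3": 1, "A4": 1}, {"A3A4": 1}, "k1"),
        Reaction({"A3A4": 1}, {"A3": 1, "A4": 1}, "k2"),
        Reaction({"A3A4": 1, "ATP": 1}, {"A3A4T": 1}, "k3"),
        Reaction({"A3A4T": 1}, {"A3A4": 1, "ATP": 1}, "k4"),
        Reaction({"A3A4T": 1}, {"A3p": 1, "A4": 1}, "k5"),
        Reaction({"A3p": 1, "Y6": 1}, {"A3": 1, "Y6p": 1}, "k6"),
        Reaction({"A3": 1, "Y6p": 1}, {"A3p": 1, "Y6": 1}, "k7"),
        Reaction({"Y6p": 1}, {"Y6": 1}, "k8"),
        Reaction({"A3": 1, "Y6p": 1}, {"A3Y6p": 1}, "k9"),
        Reaction({"A3Y6p": 1}, {"A3": 1, "Y6p": 1}, "k10"),
        Reaction({"A3Y6p": 1}, {"A3": 1, "Y6": 1}, "k11"),
    ]
    return ReactionNetwork(
        species=BASIC_SPECIES + ("ATP",),
        reactions=reactions,
        clamped={"ATP": "ATP"},
        name="basic_split_bifunctional",
    )


# ----------------------------------------------------------------------
class SignalSchedule:
    """Piecewise-constant signal k5(t).

    ``steps`` is a sequence of (start_time, k5_value); the first start time
    must be 0 and times must be increasing.
    """

    def __init__(self, steps: Sequence[Tuple[float, float]]):
        steps = [(float(t), float(v)) for t, v in steps]
        if not steps or steps[0][0] != 0.0:
            raise ValueError("schedule must start at t=0")
        times = [t for t, _ in steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")
        if any(v < 0 for _, v in steps):
            raise ValueError("signal values must be >= 0")
        self.steps: List[Tuple[float, float]] = steps

    @classmethod
    def constant(cls, k5: float) -> "SignalSchedule":
        return cls([(0.0, k5)])

    @classmethod
    def staircase(cls, values: Sequence[float], dwell: float) -> "SignalSchedule":
        """Equal-dwell staircase through ``values`` (e.g. 2→6→2)."""
        return cls([(i * dwell, v) for i, v in enumerate(values)])

    def value(self, t: float) -> float:
        v = self.steps[0][1]
        for t0, vi in self.steps:
            if t >= t0:
                v = vi
            else:
                break
        return v

    def segments(self, t_end: float) -> List[Tuple[float, float, float]]:
        """(t_start, t_stop, k5) pieces covering [0, t_end]."""
        out = []
        for i, (t0, v) in enumerate(self.steps):
            if t0 >= t_end:
                break
            t1 = self.steps[i + 1][0] if i + 1 < len(self.steps) else t_end
            out.append((t0, min(t1, t_end), v))
        return out

    def to_jsonable(self) -> List[List[float]]:
        return [[t, v] for t, v in self.steps]


@dataclass
class Trajectory:
    """Simulated time course on a fixed output grid."""

    time: np.ndarray
    states: np.ndarray                 # shape (n_times, n_species)
    species: Tuple[str, ...]
    schedule: SignalSchedule
    params: ParameterSet
    warnings: List[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def normalized(self, name: str) -> np.ndarray:
        """Species trace divided by the appropriate conserved total."""
        totals = {
            "A3": "A3_tot", "A3p": "A3_tot", "A3A4": "A3_tot",
            "A3A4T": "A3_tot", "A3Y6p": "A3_tot", "A3pA4": "A3_tot",
            "A3A4Y6p": "A3_tot", "A3A4TY6p": "A3_tot", "A3pY6p": "A3_tot",
            "A4": "A4_tot", "Y6": "Y6_tot", "Y6p": "Y6_tot",
            "A2": "A2_tot", "A2p": "A2_tot",
            "H": "H_tot", "Hp": "H_tot", "HRp": "H_tot",
            "R": "R_tot", "Rp": "R_tot",
            "Z": "Z_tot", "ZRp": "Z_tot",
        }
        return self[name] / self.params[totals[name]]

    def to_csv(self, path) -> None:
        header = "time_s," + ",".join(self.species)
        np.savetxt(
            path,
            np.column_stack([self.time, self.states]),
            delimiter=",",
            header=header,
            comments="",
        )

    def write_metadata(self, path) -> None:
        meta = {
            "schema_version": 1,
            "parameters": self.params.to_dict(),
            "schedule": self.schedule.to_jsonable(),
            "species": list(self.species),
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=2)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the failure time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


def simulate(
    network: ReactionNetwork,
    params: ParameterSet,
    schedule: SignalSchedule,
    t_grid: Sequence[float],
    init: Optional[np.ndarray] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the network under a piecewise-constant signal schedule.

    Each constant-signal segment is integrated separately with LSODA so
    the solver never steps across a discontinuity in k5.  Conservation
    drift beyond 1e-6 relative is recorded as a warning on the trajectory.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a 1-D increasing array")
    if init is None:
        init = network.initial_state(params)
    init = np.asarray(init, dtype=float)

    L = network.conservation_laws()
    totals0 = L @ init

    out = np.empty((len(t_grid), network.n_species()))
    y = init.copy()
    warnings: List[str] = []
    filled = np.zeros(len(t_grid), dtype=bool)
    if t_grid[0] == 0.0:
        out[0] = y
        filled[0] = True

    for t0, t1, k5 in schedule.segments(float(t_grid[-1])):
        seg_params = params.with_(k5=k5)
        f = network.rhs_function(seg_params)
        jac = network.jacobian_function(seg_params)
        mask = (t_grid > t0) & (t_grid <= t1) & ~filled
        t_eval = t_grid[mask]
        # always evaluate the segment end so the next piece starts exactly there
        eval_pts = np.unique(np.append(t_eval, t1))
        sol = solve_ivp(
            f, (t0, t1), y,
            method="LSODA", rtol=rtol, atol=atol, t_eval=eval_pts, jac=jac,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed at t={sol.t[-1]:.6g} s: {sol.message}",
                t_fail=float(sol.t[-1]),
            )
        if len(t_eval):
            sel = np.isin(sol.t, t_eval)
            out[mask] = sol.y[:, sel].T
            filled[mask] = True
        y = sol.y[:, -1]

    drift = np.abs(L @ out.T - totals0[:, None])
    scale = np.maximum(np.abs(totals0[:, None]), 1.0)
    if np.any(drift / scale > 1e-6):
        warnings.append(
            f"conservation drift {float((drift / scale).max()):.3g} exceeds 1e-6 relative"
        )
    return Trajectory(
        time=t_grid, states=out, species=network.dynamic_species,
        schedule=schedule, params=params, warnings=warnings,
    )


def brute_force_rhs(network: ReactionNetwork, state: np.ndarray,
                    params: ParameterSet) -> np.ndarray:
    """Term-by-term flux summation, kept deliberately naive.

    Independent of the vectorized path: walks every reaction, multiplies
    out its mass-action monomial with Python floats, and accumulates the
    stoichiometric contributions species by species.
    """
    conc = {s: float(v) for s, v in zip(network.dynamic_species, state)}
    deriv = Counter()
    for rxn in network.reactions:
        flux = float(params[rxn.rate])
        for s, c in rxn.reactants.items():
            level = params[network.clamped[s]] if s in network.clamped else conc[s]
            flux *= level ** c
        for s, c in rxn.reactants.items():
            if s not in network.clamped:
                deriv[s] -= c * flux
        for s, c in rxn.products.items():
            if s not in network.clamped:
                deriv[s] += c * flux
    return np.array([deriv[s] for s in network.dynamic_species])
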