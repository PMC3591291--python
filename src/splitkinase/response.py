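"""Steady-state signal-response analysis: curves, bistability, hysteresis.

The signal is the autophosphorylation catalytic rate k5; the response is
the steady-state level of phospho-CheY6.  Signal-response curves are
traced by a bidirectional warm-started sweep (ascending from the
unphosphorylated state, descending from the fully phosphorylated state),
each point refined by root finding on the conservation-augmented system.
Disagreement between the sweeps localizes saddle-node folds, which are
then refined by bisection; the unstable middle branch is traced by root
finding between the two stable branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import orth
from scipy.optimize import least_squares

from .network import RTOL, ATOL, ReactionNetwork, SignalSchedule, Trajectory, simulate
from .parameters import ParameterSet


class SteadyStateError(RuntimeError):
    """Non-convergence to steady state; carries the last state reached."""

    def __init__(self, message: str, last_state: np.ndarray):
        super().__init__(message)
        self.last_state = last_state


# ----------------------------------------------------------------------
# steady states and stability
# ----------------------------------------------------------------------
def _augmented_residual(network: ReactionNetwork, params: ParameterSet,
                        L: np.ndarray, totals: np.ndarray):
    k = network.rate_vector(params)
    N = network.stoichiometry

    def F(y: np.ndarray) -> np.ndarray:
        return np.concatenate([N @ network.fluxes(y, k), L @ y - totals])

    return F


def refine_root(
    network: ReactionNetwork,
    params: ParameterSet,
    guess: np.ndarray,
    totals: Optional[np.ndarray] = None,
    fast: bool = False,
) -> Optional[np.ndarray]:
    """Solve rhs=0 within the conserved class of ``guess`` (or ``totals``).

    Returns the root, or None if the solver fails to reach a residual
    compatible with a steady state.  ``fast=True`` tries an unconstrained
    Levenberg–Marquardt solve first (used by the multistart screens,
    where throughput matters) and falls back to the bounded solver.
    """
    L = network.conservation_laws()
    if totals is None:
        totals = L @ np.asarray(guess, dtype=float)
    F = _augmented_residual(network, params, L, totals)
    y0 = np.maximum(np.asarray(guess, dtype=float), 0.0)
    if fast:
        sol = least_squares(F, y0, method="lm", xtol=1e-12, ftol=1e-12,
                            max_nfev=300)
        x = sol.x
        if np.all(x > -1e-9):
            x = np.maximum(x, 0.0)
            if np.linalg.norm(F(x)) < 1e-8 * (1.0 + np.linalg.norm(x)):
                return x
        sol = least_squares(F, y0, bounds=(0.0, np.inf), method="trf",
                            xtol=1e-10, ftol=1e-12, gtol=1e-12, max_nfev=150)
        x = np.maximum(sol.x, 0.0)
        if np.linalg.norm(F(x)) < 1e-8 * (1.0 + np.linalg.norm(x)):
            return x
        return None
    sol = least_squares(
        F, y0, bounds=(0.0, np.inf), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
    )
    x = _newton_polish(network, params, F, sol.x)
    scale = 1.0 + np.linalg.norm(x)
    if np.linalg.norm(F(x)) < 1e-8 * scale:
        return x
    return None


def _newton_polish(network, params, F, x, iters: int = 3) -> np.ndarray:
    """Gauss–Newton steps on the augmented residual to tighten the root.

    Near a fold the trust-region solver stagnates above round-off; a few
    explicit least-squares Newton steps recover full precision when they
    help and are discarded when they do not.
    """
    best, best_r = x, np.linalg.norm(F(x))
    for _ in range(iters):
        J = _fd_jacobian_vec(F, x)
        step, *_ = np.linalg.lstsq(J, -F(x), rcond=None)
        cand = np.maximum(x + step, 0.0)
        r = np.linalg.norm(F(cand))
        if not np.isfinite(r) or r >= best_r:
            break
        x, best, best_r = cand, cand, r
    return best


def _fd_jacobian_vec(F, x, rel_step: float = 1e-7) -> np.ndarray:
    f0 = F(x)
    J = np.empty((len(f0), len(x)))
    for j in range(len(x)):
        h = rel_step * max(abs(x[j]), 1e-3)
        xp = x.copy()
        xp[j] += h
        J[:, j] = (F(xp) - f0) / h
    return J


def jacobian(network: ReactionNetwork, params: ParameterSet,
             state: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of the mass-action RHS."""
    y = np.asarray(state, dtype=float)
    f = network.rhs_function(params)
    n = len(y)
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (f(0.0, yp) - f(0.0, ym)) / (2 * h)
    return J


def _stoich_basis(network: ReactionNetwork) -> np.ndarray:
    if not hasattr(network, "_orth_cache"):
        network._orth_cache = orth(network.stoichiometry)
    return network._orth_cache


def reduced_eigenvalues(network: ReactionNetwork, params: ParameterSet,
                        state: np.ndarray) -> np.ndarray:
    """Jacobian eigenvalues restricted to the stoichiometric subspace.

    Projecting onto range(N) removes the structural zero eigenvalues
    contributed by the conserved moieties.
    """
    Q = _stoich_basis(network)
    J = jacobian(network, params, state)
    return np.linalg.eigvals(Q.T @ J @ Q)


def is_stable(network: ReactionNetwork, params: ParameterSet,
              state: np.ndarray, tol: float = 1e-7) -> bool:
    return bool(np.max(reduced_eigenvalues(network, params, state).real) < tol)


def steady_state(
    network: ReactionNetwork,
    params: ParameterSet,
    k5: Optional[float] = None,
    init: Optional[np.ndarray] = None,
    t_max: float = 1e6,
    rhs_tol: float = 1e-10,
) -> np.ndarray:
    """Steady state in the basin of ``init`` at a fixed signal level.

    Integrates in geometrically growing chunks until ``||rhs|| <
    rhs_tol*(1+||y||)``, then polishes with root finding on the
    conservation-reduced system.  Raises :class:`SteadyStateError` if the
    residual criterion is not reached by ``t_max`` seconds and root
    refinement from the last state also fails.
    """
    if k5 is not None:
        params = params.with_(k5=k5)
    y = network.initial_state(params) if init is None else np.asarray(init, dtype=float)
    totals = network.conserved_totals(y)
    f = network.rhs_function(params)
    jac = network.jacobian_function(params)
    t, chunk = 0.0, 1e2
    while t < t_max:
        res = np.linalg.norm(network.rhs(y, params))
        if res < rhs_tol * (1.0 + np.linalg.norm(y)):
            break
        sol = solve_ivp(f, (0.0, chunk), y, method="LSODA", rtol=RTOL, atol=ATOL,
                        jac=jac)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}", y)
        y = sol.y[:, -1]
        t += chunk
        chunk = min(chunk * 4.0, t_max - t) or chunk
    root = refine_root(network, params, y, totals=totals)
    if root is None:
        res = np.linalg.norm(network.rhs(y, params))
        if res < rhs_tol * (1.0 + np.linalg.norm(y)):
            return y
        raise SteadyStateError(
            f"no steady state within t_max={t_max:g} s (||rhs||={res:.3g})", y
        )
    return root


# ----------------------------------------------------------------------
# signal-response curves
# ----------------------------------------------------------------------
@dataclass
class SignalResponseCurve:
    """Bidirectional steady-state sweep of the response against signal k5."""

    k5: np.ndarray                         # signal grid, 1/s
    ascending: np.ndarray                  # states (n, n_species), low-init sweep
    descending: np.ndarray                 # states (n, n_species), high-init sweep
    species: Tuple[str, ...]
    response_species: str
    response_total: float                  # normalizer (e.g. Y6_tot), µM
    params: ParameterSet
    folds: Optional[Tuple[float, float]] = None   # (k5_low, k5_high), ordered
    unstable_k5: np.ndarray = field(default_factory=lambda: np.empty(0))
    unstable_states: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    gaps: List[float] = field(default_factory=list)  # k5 values where a sweep failed

    def _resp(self, states: np.ndarray) -> np.ndarray:
        return states[:, self.species.index(self.response_species)]

    @property
    def response_up(self) -> np.ndarray:
        """Response along the ascending sweep (µM)."""
        return self._resp(self.ascending)

    @property
    def response_down(self) -> np.ndarray:
        return self._resp(self.descending)

    @property
    def unstable_response(self) -> np.ndarray:
        if self.unstable_states.size == 0:
            return np.empty(0)
        return self._resp(self.unstable_states)

    def normalized_up(self) -> np.ndarray:
        return self.response_up / self.response_total

    def normalized_down(self) -> np.ndarray:
        return self.response_down / self.response_total

    @property
    def bistable(self) -> bool:
        return detect_bistability(self)[0]

    def to_frame(self):
        """Long-format table: k5, branch_id, stability, response."""
        import pandas as pd

        rows = []
        for branch, k5s, resps, stab in (
            ("ascending", self.k5, self.response_up, "stable"),
            ("descending", self.k5, self.response_down, "stable"),
            ("unstable", self.unstable_k5, self.unstable_response, "unstable"),
        ):
            for k, r in zip(k5s, resps):
                rows.append(
                    {"k5": k, "branch_id": branch, "stability": stab,
                     "Y6p_uM": r, "Y6p_norm": r / self.response_total}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def report(self) -> dict:
        bist, folds = detect_bistability(self)
        return {
            "schema_version": 1,
            "bistable": bool(bist),
            "folds_k5": list(folds) if folds else None,
            "k5_range": [float(self.k5[0]), float(self.k5[-1])],
            "n_points": int(len(self.k5)),
            "gaps": list(self.gaps),
            "parameters": self.params.to_dict(),
        }


def _sweep(
    network: ReactionNetwork,
    params: ParameterSet,
    k5_grid: np.ndarray,
    start: np.ndarray,
    settle_time: float,
) -> Tuple[np.ndarray, List[float]]:
    """Warm-started branch following along a signal grid.

    At each grid point, try a root refinement from the previous state; if
    the refined root is unstable or the solver fails (the branch has
    folded), relax by integration from the previous state instead, which
    lands on the stable state in its basin.
    """
    states = np.empty((len(k5_grid), network.n_species()))
    gaps: List[float] = []
    y = start.copy()
    totals = network.conserved_totals(y)
    for i, k5 in enumerate(k5_grid):
        p = params.with_(k5=k5)
        root = refine_root(network, p, y, totals=totals)
        if root is not None and not is_stable(network, p, root):
            root = None
        if root is None or np.max(np.abs(root - y)) > 0.25 * (1.0 + np.max(np.abs(y))):
            # fold passed (or big jump): settle dynamically from warm start
            try:
                root = steady_state(network, p, init=y, t_max=settle_time)
            except SteadyStateError as err:
                gaps.append(float(k5))
                root = err.last_state
        states[i] = root
        y = root
    return states, gaps


def scan_signal_response(
    network: ReactionNetwork,
    params: ParameterSet,
    k5_range: Tuple[float, float] = (0.0, 10.0),
    n_points: int = 500,
    response_species: str = "Y6p",
    response_total_label: str = "Y6_tot",
    refine_folds: bool = True,
    refine_slope: bool = True,
    settle_time: float = 1e6,
    low_init: Optional[np.ndarray] = None,
    high_init: Optional[np.ndarray] = None,
) -> SignalResponseCurve:
    """Trace the signal-response curve over ``k5_range``.

    Ascending sweep starts from the unphosphorylated state, descending
    from the fully phosphorylated one.  Where the sweeps disagree the two
    saddle-node folds are refined by bisection to 1e-4 relative in k5 and
    the unstable branch is traced between them.  ``refine_slope`` adds a
    10x denser sub-grid around the maximum-slope region so the
    sigmoidality metric sees a well-resolved shoulder.
    """
    lo, hi = map(float, k5_range)
    if lo < 0 or hi <= lo:
        raise ValueError("k5_range must be nonnegative and increasing")
    grid = np.linspace(lo, hi, int(n_points))

    if low_init is None:
        low_init = network.initial_state(params, phospho=False)
    if high_init is None:
        high_init = network.initial_state(params, phospho=True)
    low_start = steady_state(network, params.with_(k5=grid[0]), init=low_init)
    high_start = steady_state(network, params.with_(k5=grid[-1]), init=high_init)

    up, gaps_up = _sweep(network, params, grid, low_start, settle_time)
    down_rev, gaps_down = _sweep(network, params, grid[::-1], high_start, settle_time)
    down = down_rev[::-1]

    curve = SignalResponseCurve(
        k5=grid, ascending=up, descending=down,
        species=network.dynamic_species, response_species=response_species,
        response_total=params[response_total_label], params=params,
        gaps=gaps_up + gaps_down,
    )

    if refine_slope:
        _refine_max_slope(network, params, curve, settle_time)

    bistable, _ = detect_bistability(curve, folds_known=False)
    if bistable and refine_folds:
        folds = refine_fold_pair(network, params, curve)
        curve.folds = folds
        if folds is not None:
            _trace_unstable(network, params, curve)
    return curve


def _refine_max_slope(network, params, curve, settle_time, factor: int = 10):
    """Insert a denser sub-grid around the steepest ascending segment."""
    resp = curve.response_up
    slopes = np.abs(np.diff(resp) / np.diff(curve.k5))
    j = int(np.argmax(slopes))
    j0, j1 = max(j - 1, 0), min(j + 2, len(curve.k5) - 1)
    sub = np.linspace(curve.k5[j0], curve.k5[j1], factor * (j1 - j0) + 1)
    # drop points (numerically) coinciding with the existing grid: near-zero
    # spacing corrupts finite-difference slopes downstream
    tol = 1e-8 * (curve.k5[-1] - curve.k5[0])
    dist = np.min(np.abs(sub[:, None] - curve.k5[None, :]), axis=1)
    sub = sub[dist > tol]
    if len(sub) == 0:
        return
    up_sub, _ = _sweep(network, params, sub, curve.ascending[j0], settle_time)
    down_sub, _ = _sweep(network, params, sub[::-1], curve.descending[j1], settle_time)
    k5_new = np.concatenate([curve.k5, sub])
    order = np.argsort(k5_new, kind="stable")
    curve.k5 = k5_new[order]
    curve.ascending = np.vstack([curve.ascending, up_sub])[order]
    curve.descending = np.vstack([curve.descending, down_sub[::-1]])[order]


def detect_bistability(
    curve: SignalResponseCurve, folds_known: bool = True
) -> Tuple[bool, Optional[Tuple[float, float]]]:
    """Bistability flag and ordered fold pair from a traced curve.

    Bistable iff the two sweeps disagree by more than 1% of the response
    total anywhere, or an unstable branch was traced.
    """
    gap = np.abs(curve.response_up - curve.response_down)
    disagree = bool(np.any(gap > 0.01 * curve.response_total))
    has_unstable = curve.unstable_k5.size > 0
    bistable = disagree or has_unstable
    folds = curve.folds if folds_known else None
    if bistable and folds is None:
        mask = gap > 0.01 * curve.response_total
        folds = (float(curve.k5[mask][0]), float(curve.k5[mask][-1]))
    if folds is not None:
        folds = (min(folds), max(folds))
    return bistable, folds


def _branch_exists(network, params, k5, ref_state, other_state) -> Optional[np.ndarray]:
    """Root continuation test: does the branch through ``ref_state`` persist?

    Returns the continued root if a stable root closer to ``ref_state``
    than to ``other_state`` (in response coordinate) exists at ``k5``.
    """
    p = params.with_(k5=k5)
    root = refine_root(network, p, ref_state)
    if root is None or not is_stable(network, p, root):
        return None
    d_ref = np.linalg.norm(root - ref_state)
    d_other = np.linalg.norm(root - other_state)
    return root if d_ref < d_other else None


def refine_fold_pair(network, params, curve,
                     rel_tol: float = 1e-4) -> Optional[Tuple[float, float]]:
    """Bisect the two saddle-node signal values bracketed by the sweeps.

    ``rel_tol`` is relative in k5; tighter values localize the fold far
    enough that the critical eigenvalue (which scales as the square root
    of the distance to the fold) becomes correspondingly small.
    """
    gap = np.abs(curve.response_up - curve.response_down)
    mask = gap > 0.01 * curve.response_total
    if not np.any(mask):
        return None
    idx = np.flatnonzero(mask)
    i_lo, i_hi = idx[0], idx[-1]

    # upper fold: low branch dies between grid[i_hi] and grid[i_hi + 1]
    def bisect(a, b, ref, other):
        ka, kb = a, b
        while (kb - ka) > rel_tol * max(kb, 1e-12):
            km = 0.5 * (ka + kb)
            root = _branch_exists(network, params, km, ref, other)
            if root is not None:
                ka, ref = km, root
            else:
                kb = km
        return 0.5 * (ka + kb)

    try:
        hi_a = float(curve.k5[i_hi])
        hi_b = float(curve.k5[min(i_hi + 1, len(curve.k5) - 1)])
        fold_hi = bisect(hi_a, max(hi_b, hi_a * (1 + 10 * rel_tol)),
                         curve.ascending[i_hi], curve.descending[i_hi])

        lo_a = float(curve.k5[i_lo])
        lo_b = float(curve.k5[max(i_lo - 1, 0)])

        # descend: high branch dies between grid[i_lo - 1] and grid[i_lo]
        def bisect_down(a, b, ref, other):
            ka, kb = a, b  # ka: exists (higher k5), kb: lower bound
            while (ka - kb) > rel_tol * max(ka, 1e-12):
                km = 0.5 * (ka + kb)
                root = _branch_exists(network, params, km, ref, other)
                if root is not None:
                    ka, ref = km, root
                else:
                    kb = km
            return 0.5 * (ka + kb)

        fold_lo = bisect_down(lo_a, lo_b, curve.descending[i_lo], curve.ascending[i_lo])
    except Exception:
        return (float(curve.k5[i_lo]), float(curve.k5[i_hi]))
    return (min(fold_lo, fold_hi), max(fold_lo, fold_hi))


def _trace_unstable(network, params, curve) -> None:
    """Root-find the unstable middle branch between the folds."""
    f_lo, f_hi = curve.folds
    inside = (curve.k5 > f_lo) & (curve.k5 < f_hi)
    ks, states = [], []
    for i in np.flatnonzero(inside):
        p = params.with_(k5=float(curve.k5[i]))
        guess = 0.5 * (curve.ascending[i] + curve.descending[i])
        root = refine_root(network, p, guess)
        if root is None:
            continue
        if is_stable(network, p, root):
            continue
        lo, hi = curve.response_up[i], curve.response_down[i]
        r = root[curve.species.index(curve.response_species)]
        if min(lo, hi) - 1e-6 <= r <= max(lo, hi) + 1e-6:
            ks.append(float(curve.k5[i]))
            states.append(root)
    if ks:
        curve.unstable_k5 = np.array(ks)
        curve.unstable_states = np.array(states)


# ----------------------------------------------------------------------
# hysteresis protocol
# ----------------------------------------------------------------------
@dataclass
class HysteresisResult:
    trajectory: Trajectory
    ascent_threshold: Optional[float]      # k5 at which response crosses 0.5 going up
    descent_threshold: Optional[float]
    segment_k5: np.ndarray
    segment_response: np.ndarray           # normalized response at segment ends
    reliable: bool


def hysteresis_timecourse(
    network: ReactionNetwork,
    params: ParameterSet,
    values: Sequence[float] = (2, 3, 4, 5, 6, 5, 4, 3, 2),
    dwell: float = 2000.0,
    response_species: str = "Y6p",
    response_total_label: str = "Y6_tot",
    n_per_segment: int = 40,
    settle_tol: float = 1e-6,
) -> HysteresisResult:
    """Step the signal up and back down and locate the switching thresholds.

    The signal follows an equal-dwell staircase (default 2→6→2 in unit
    steps).  The threshold on each leg is the signal at which the settled
    (end-of-dwell) normalized response crosses 0.5, linearly interpolated
    between the bracketing signal levels; ascent > descent indicates
    hysteresis, while on a monostable system the two legs retrace the same
    single-valued curve and the thresholds coincide.  A dwell too short to
    settle (``||rhs||`` above ``settle_tol`` at a segment end) marks the
    thresholds unreliable.
    """
    values = list(values)
    schedule = SignalSchedule.staircase(values, dwell)
    t_end = dwell * len(values)
    t_grid = np.linspace(0.0, t_end, n_per_segment * len(values) + 1)
    traj = simulate(network, params, schedule, t_grid)

    total = params[response_total_label]
    end_times = np.array([(i + 1) * dwell for i in range(len(values))])
    end_idx = np.searchsorted(t_grid, end_times - 1e-9, side="left")
    end_idx = np.minimum(end_idx, len(t_grid) - 1)
    resp = traj[response_species][end_idx] / total

    reliable = True
    for i, j in enumerate(end_idx):
        p = params.with_(k5=values[i])
        r = np.linalg.norm(network.rhs(traj.states[j], p))
        if r > settle_tol * (1.0 + np.linalg.norm(traj.states[j])):
            reliable = False

    i_peak = int(np.argmax(values))
    up_vals, up_resp = values[: i_peak + 1], resp[: i_peak + 1]
    down_vals, down_resp = values[i_peak:], resp[i_peak:]

    def interp_crossing(vals, rs, rising: bool):
        for a in range(1, len(vals)):
            r0, r1, v0, v1 = rs[a - 1], rs[a], vals[a - 1], vals[a]
            hit = (r0 < 0.5 <= r1) if rising else (r0 >= 0.5 > r1)
            if hit:
                return float(v0 + (0.5 - r0) / (r1 - r0) * (v1 - v0))
        return None

    ascent = interp_crossing(up_vals, up_resp, rising=True)
    descent = interp_crossing(down_vals, down_resp, rising=False)
    return HysteresisResult(
        trajectory=traj,
        ascent_threshold=ascent,
        descent_threshold=descent,
        segment_k5=np.array(values, dtype=float),
        segment_response=resp,
        reliable=reliable,
    )
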