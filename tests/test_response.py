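import numpy as np
import pytest

from splitkinase import (
    ParameterSet,
    detect_bistability,
    hysteresis_timecourse,
    scan_signal_response,
    steady_state,
)
from splitkinase.crnt import random_states_in_class
from splitkinase.network import SignalSchedule, simulate
from splitkinase.response import reduced_eigenvalues, refine_root


def test_zero_signal_steady_state_is_unphosphorylated(basic_network, base_params):
    ss = steady_state(basic_network, base_params, k5=0.0)
    for sp in ("Y6p", "A3p", "A3Y6p"):
        assert ss[basic_network.species_index(sp)] == pytest.approx(0.0, abs=1e-8)


def test_two_basins_inside_bistable_window(basic_network, base_params):
    low = steady_state(basic_network, base_params, k5=5.0)
    high = steady_state(basic_network, base_params, k5=5.0,
                        init=basic_network.initial_state(base_params, phospho=True))
    i = basic_network.species_index("Y6p")
    assert high[i] - low[i] > 0.1 * base_params.Y6_tot


def test_refined_root_agrees_with_long_integration(basic_network, base_params):
    params = base_params.with_(k5=3.0)
    f = basic_network.rhs_function(params)
    from scipy.integrate import solve_ivp

    y0 = basic_network.initial_state(params)
    sol = solve_ivp(f, (0.0, 1e5), y0, method="LSODA", rtol=1e-10, atol=1e-12,
                    jac=basic_network.jacobian_function(params))
    ss = steady_state(basic_network, base_params, k5=3.0)
    assert np.max(np.abs(ss - sol.y[:, -1])) < 1e-6


def test_default_scan_is_bistable_with_two_folds(default_curve):
    bistable, folds = detect_bistability(default_curve)
    assert bistable
    assert folds is not None and folds[0] < folds[1]
    # unstable middle branch traced between the folds, between the stable
    # branches in the response coordinate
    assert default_curve.unstable_k5.size > 0
    for k5, r in zip(default_curve.unstable_k5, default_curve.unstable_response):
        i = np.argmin(np.abs(default_curve.k5 - k5))
        lo = min(default_curve.response_up[i], default_curve.response_down[i])
        hi = max(default_curve.response_up[i], default_curve.response_down[i])
        assert lo - 1e-6 <= r <= hi + 1e-6


def test_unstable_branch_points_have_positive_eigenvalue(
        basic_network, base_params, default_curve):
    for k5, state in list(zip(default_curve.unstable_k5,
                              default_curve.unstable_states))[::5]:
        lam = reduced_eigenvalues(basic_network, base_params.with_(k5=float(k5)), state)
        assert lam.real.max() > 0


def test_fold_is_a_saddle_node(basic_network, base_params, default_curve):
    """At a tightly localized fold the reduced Jacobian eigenvalue crosses 0.

    The critical eigenvalue shrinks as sqrt(distance to the fold), so the
    bisection is pushed to 1e-9 relative in k5 for this check.
    """
    from splitkinase.response import refine_fold_pair

    folds = refine_fold_pair(basic_network, base_params, default_curve,
                             rel_tol=1e-9)
    assert folds is not None
    k5_fold = folds[1]
    i = np.searchsorted(default_curve.k5, k5_fold) - 1
    # evaluate a hair inside the fold, where the merging root still exists
    root = None
    for eps in (1e-8, 1e-7, 1e-6):
        p = base_params.with_(k5=k5_fold * (1.0 - eps))
        root = refine_root(basic_network, p, default_curve.ascending[i])
        if root is not None:
            break
    assert root is not None
    lam = reduced_eigenvalues(basic_network, p, root)
    assert np.min(np.abs(lam.real)) < 1e-4


def test_weak_association_is_monostable(monostable_curve):
    bistable, _ = detect_bistability(monostable_curve)
    assert not bistable


def test_sweeps_agree_on_monostable_curve(monostable_curve):
    gap = np.abs(monostable_curve.response_up - monostable_curve.response_down)
    assert gap.max() < 1e-6


@pytest.mark.parametrize("a4_tot", [30.0, 80.0])
def test_chea4_level_reshapes_the_curve(basic_network, base_params,
                                        default_curve, a4_tot):
    curve = scan_signal_response(
        basic_network, base_params.with_(A4_tot=a4_tot), (0.0, 10.0),
        n_points=60, refine_folds=False, refine_slope=False,
    )
    ref = np.interp(curve.k5, default_curve.k5, default_curve.response_up)
    assert np.max(np.abs(curve.response_up - ref)) > 1.0  # µM: clearly distinct


def test_basin_dichotomy_inside_window(basic_network, base_params, rng):
    """Random conserved-class initial conditions all reach one of two states."""
    k5 = 5.0
    params = base_params.with_(k5=k5)
    low = steady_state(basic_network, base_params, k5=k5)
    high = steady_state(basic_network, base_params, k5=k5,
                        init=basic_network.initial_state(base_params, phospho=True))
    anchor = 0.5 * (basic_network.initial_state(params)
                    + basic_network.initial_state(params, phospho=True))
    starts = random_states_in_class(basic_network, anchor, 20, rng)
    for y0 in starts:
        ss = steady_state(basic_network, params, init=y0)
        d_low = np.max(np.abs(ss - low))
        d_high = np.max(np.abs(ss - high))
        assert min(d_low, d_high) < 1e-4


def test_hysteresis_thresholds_asymmetric_at_base_parameters(
        basic_network, base_params):
    result = hysteresis_timecourse(basic_network, base_params)
    assert result.reliable
    assert result.ascent_threshold is not None
    assert result.descent_threshold is not None
    assert result.ascent_threshold > result.descent_threshold + 0.1


def test_free_chea3_collapse_coincides_with_upswitch(basic_network, base_params):
    """The up-switch in CheY6-P coincides with depletion of free CheA3.

    Compared segment by segment on the ascent: while the settled response
    is still low there is ample free CheA3; in the segment where the
    response switches high, free CheA3 has collapsed.
    """
    result = hysteresis_timecourse(basic_network, base_params)
    traj = result.trajectory
    dwell = 2000.0
    values = result.segment_k5
    i_peak = int(np.argmax(values))
    y6p_end, a3_end = [], []
    for seg in range(i_peak + 1):
        j = np.searchsorted(traj.time, (seg + 1) * dwell - 1e-9)
        j = min(j, len(traj.time) - 1)
        y6p_end.append(traj.normalized("Y6p")[j])
        a3_end.append(traj.normalized("A3")[j])
    y6p_end, a3_end = np.array(y6p_end), np.array(a3_end)
    switch = int(np.argmax(np.diff(y6p_end))) + 1
    assert y6p_end[switch] - y6p_end[switch - 1] > 0.2   # abrupt up-switch
    assert a3_end[switch] < 0.05                          # free CheA3 collapsed
    assert a3_end[0] > 0.1                                # ample before the ascent
    # the decline of free CheA3 is monotone along the ascent: the branch
    # point drains as signal rises
    assert np.all(np.diff(a3_end) < 0.0)


def test_monostable_thresholds_coincide(basic_network, base_params):
    """Without bistability the two legs retrace one curve: no hysteresis.

    Uses the weak-phosphatase monostable case (k11 = 1/s), whose response
    does cross half-saturation inside the stepped signal range.
    """
    params = base_params.with_(k11=1.0)
    result = hysteresis_timecourse(basic_network, params)
    assert result.ascent_threshold is not None
    assert result.descent_threshold is not None
    assert result.ascent_threshold == pytest.approx(result.descent_threshold,
                                                    abs=1e-3)


def test_short_dwell_flags_unreliable(basic_network, base_params):
    result = hysteresis_timecourse(basic_network, base_params,
                                   values=(2, 6, 2), dwell=1.0)
    assert not result.reliable
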