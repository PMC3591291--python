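import numpy as np
import pytest

from splitkinase import (
    ParameterSet,
    build_invitro_network,
    fit_kobs,
    fit_phosphatase_params,
    predict_kobs_curve,
    simulate_assay,
)
from splitkinase.invitro import (
    A3_0,
    P1P_0,
    Y6_0,
    assay_initial_state,
    invitro_parameters,
)
from splitkinase.synthetic import NoiseModel, gen_decay_dataset

FIT_T_GRID = np.linspace(0.0, 12.0, 25)
FIT_PANEL = (0.0, 20.0, 60.0)


def test_invitro_network_has_no_kinase_reactions():
    net = build_invitro_network()
    rates = {r.rate for r in net.reactions}
    assert {"k6", "k7", "k8", "k9", "k10", "k11", "k1_iv", "k2"} == rates
    assert not net.clamped  # ATP was removed during purification
    # free CheA4 inert toward CheY6-P: no reaction consumes both
    for rxn in net.reactions:
        assert not ({"A4", "Y6p"} <= set(rxn.reactants))


def test_transfer_completes_early_and_loads_y6p():
    ds = simulate_assay()
    assert all(f > 0.95 for f in ds.metadata["transfer_fraction_by_10s"].values())
    for cid, sub in ds.conditions():
        early = sub[(sub.time_s > 0.2) & (sub.time_s <= 0.6)]
        assert early["Y6p_signal"].max() > 0.9 * P1P_0


def test_kobs_flat_without_chea3():
    table = predict_kobs_curve(A4_range=(0.0, 20.0, 40.0, 60.0), a3_present=False)
    k = table["k_obs"].to_numpy()
    assert np.all(np.abs(k / k[0] - 1.0) < 0.01)
    # decay floor is the autodephosphorylation rate
    assert k[0] == pytest.approx(ParameterSet().k8, rel=0.05)


def test_kobs_decreases_with_chea4_when_chea3_present():
    table = predict_kobs_curve(A4_range=(0.0, 10.0, 20.0, 40.0, 60.0))
    k = table["k_obs"].to_numpy()
    assert np.all(np.diff(k) < 0.0)
    flat = predict_kobs_curve(A4_range=(0.0,), a3_present=False)["k_obs"].iloc[0]
    assert k[0] > flat  # CheA3 adds phosphatase decay on top of the intrinsic rate


def test_sequestration_limit_approaches_chea3_free_rate():
    """With tight CheA4 binding and excess CheA4, CheA3 is fully sequestered."""
    tight = ParameterSet().with_(k1_iv=50.0)
    with_a3 = predict_kobs_curve(tight, A4_range=(2000.0,))["k_obs"].iloc[0]
    without = predict_kobs_curve(tight, A4_range=(2000.0,),
                                 a3_present=False)["k_obs"].iloc[0]
    assert with_a3 >= without - 1e-3
    assert with_a3 == pytest.approx(without, rel=0.05)


def test_kobs_monotone_under_parameter_perturbation(rng):
    """k_obs(A4) stays non-increasing across ±20% kinetic perturbations."""
    for _ in range(10):
        factors = rng.uniform(0.8, 1.2, 6)
        p = ParameterSet().with_(
            k6=0.775 * factors[0], k7=0.00283 * factors[1],
            k8=0.169 * factors[2], k9=5.6 * factors[3],
            k10=0.04 * factors[4], k11=2.5 * factors[5],
        )
        k = predict_kobs_curve(p, A4_range=(0.0, 30.0, 60.0))["k_obs"].to_numpy()
        assert np.all(np.diff(k) <= 1e-9)


def test_grid_refinement_converged():
    coarse = np.linspace(0.0, 12.0, 61)
    fine = np.linspace(0.0, 12.0, 121)
    ds_c = simulate_assay(A4_panel=(20.0,), t_grid=coarse)
    ds_f = simulate_assay(A4_panel=(20.0,), t_grid=fine)
    yc = ds_c.frame["Y6p_signal"].to_numpy()
    yf = ds_f.frame.set_index("time_s").loc[coarse, "Y6p_signal"].to_numpy()
    assert np.max(np.abs(yc - yf)) < 1e-6


def test_fit_kobs_exact_on_pure_exponential():
    t = np.linspace(0.0, 40.0, 30)
    k, resid, warn = fit_kobs(t, 30.0 * np.exp(-0.1 * t), t_start=0.0)
    assert k == pytest.approx(0.1, abs=1e-10)
    assert resid < 1e-18
    assert warn is None


def test_fit_kobs_degenerate_series():
    t = np.linspace(0.0, 10.0, 8)
    k, _, warn = fit_kobs(t, np.full(8, 5.0), t_start=0.0)
    assert k == 0.0 and warn is not None
    with pytest.raises(ValueError):
        fit_kobs(t[:3], np.ones(3))
    with pytest.raises(ValueError):
        fit_kobs(t, -np.ones(8))


def test_fit_kobs_agrees_with_loglinear_tail():
    """Exponential LSQ vs an independent log-linear regression on the tail."""
    ds = simulate_assay(A4_panel=(40.0,), t_grid=np.linspace(0.0, 20.0, 81))
    sub = ds.frame
    t, y = sub["time_s"].to_numpy(), sub["Y6p_signal"].to_numpy()
    # tail: past the saturated phase, decay is first order
    mask = (y > 1e-6 * y.max()) & (t > 6.0) & (y < 1.0)
    slope, _ = np.polyfit(t[mask], np.log(y[mask]), 1)
    k_tail = -slope
    k_fit, _, _ = fit_kobs(t, y, t_start=6.0)
    assert k_fit == pytest.approx(k_tail, rel=0.05)


def test_phosphatase_recovery_identifiability_probe():
    """Without catalysis (k11=0) the fitted k11 collapses to ~0 and k9 is flat.

    Binding without hydrolysis does not change the measured total
    phospho-CheY6, so k9 carries no information in that limit.
    """
    truth = ParameterSet().with_(k11=0.0)
    ds = gen_decay_dataset(truth, A4_panel=FIT_PANEL, t_grid=FIT_T_GRID,
                           noise=NoiseModel(kind="none", sigma=0.0))
    fit = fit_phosphatase_params(ds, seed=5, de_maxiter=6, de_popsize=5)
    assert fit.k11 < 0.05  # pinned near the lower bound, ~2% of the base value
    assert "k9" in fit.weakly_identified


def test_fit_is_seed_reproducible():
    ds = gen_decay_dataset(A4_panel=(0.0, 60.0), t_grid=FIT_T_GRID,
                           noise=NoiseModel(sigma=0.05, seed=9))
    f1 = fit_phosphatase_params(ds, seed=11, de_maxiter=4, de_popsize=4)
    f2 = fit_phosphatase_params(ds, seed=11, de_maxiter=4, de_popsize=4)
    assert f1.as_tuple() == f2.as_tuple()


def test_fit_input_validation():
    ds = gen_decay_dataset(A4_panel=(0.0,), t_grid=FIT_T_GRID,
                           noise=NoiseModel(kind="none", sigma=0.0))
    with pytest.raises(ValueError):
        fit_phosphatase_params(ds)  # single condition
    ds2 = gen_decay_dataset(A4_panel=(0.0, 60.0), t_grid=FIT_T_GRID,
                            noise=NoiseModel(kind="none", sigma=0.0))
    with pytest.raises(ValueError):
        fit_phosphatase_params(ds2, bounds=((0.0, 1.0), (1e-3, 1.0), (1e-2, 10.0)))


def test_dataset_csv_roundtrip(tmp_path):
    from splitkinase import AssayDataset

    ds = simulate_assay(A4_panel=(0.0, 30.0), t_grid=np.linspace(0.0, 10.0, 21))
    path = tmp_path / "decay.csv"
    ds.to_csv(path)
    back = AssayDataset.from_csv(path)
    assert list(back.frame.columns) == list(ds.frame.columns)
    assert np.allclose(back.frame["Y6p_signal"], ds.frame["Y6p_signal"])


def test_assay_initial_state_matches_protocol():
    net = build_invitro_network()
    y = assay_initial_state(net, A4=40.0)
    assert y[net.species_index("Y6")] == Y6_0
    assert y[net.species_index("P1p")] == P1P_0
    assert y[net.species_index("A3")] == A3_0
    assert y[net.species_index("A4")] == 40.0
    assert y[net.species_index("Y6p")] == 0.0
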