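"""PDE solver versus grid-free oracles, conservation, and scaling laws."""

import numpy as np
import pytest

import gutsim as g
from gutsim import ConfigurationError, DomainError
from gutsim.oracles import model1_closed_form, model2_quadrature, model3_characteristics
from gutsim.properties import absorption_rate_constant
from gutsim.solver import DEFAULT_L0, Grid, build_grid, initial_bolus


# ---------------------------------------------------------------- grid/bolus

def test_build_grid_uniform(geometry):
    grid = build_grid(geometry, g.GridSpec(n_cells=285))
    assert grid.dz == pytest.approx(0.01)
    np.testing.assert_allclose(grid.centers[:2], [0.005, 0.015])
    assert grid.total_volume == pytest.approx(2.90e-3, rel=2e-3)
    assert grid.n_cells * grid.cell_volume == pytest.approx(grid.total_volume, rel=1e-12)


def test_grid_too_coarse_rejected():
    with pytest.raises(ConfigurationError, match="n_cells"):
        g.GridSpec(n_cells=10)


def test_initial_bolus_concentration_and_mass(geometry, default_grid):
    grid = build_grid(geometry, default_grid)
    state = initial_bolus(50.0, DEFAULT_L0, grid)
    assert state.glucose_conc.max() == pytest.approx(1.00e6, rel=5e-3)
    total = state.glucose_conc.sum() * grid.cell_volume
    assert total == pytest.approx(50.0, rel=1e-12)


def test_initial_bolus_half_domain(geometry):
    grid = build_grid(geometry, g.GridSpec(n_cells=100))
    state = initial_bolus(10.0, geometry.length / 2, grid)
    assert np.count_nonzero(state.glucose_conc) == 50


def test_initial_bolus_outside_domain(geometry, default_grid):
    grid = build_grid(geometry, default_grid)
    with pytest.raises(DomainError, match="l0"):
        initial_bolus(10.0, geometry.length * 2, grid)


# --------------------------------------------------------- Michaelis-Menten

def test_michaelis_menten_algebra(amylase):
    vmax, km = amylase.vmax, amylase.km
    assert g.michaelis_menten_rate(km, amylase) == pytest.approx(vmax / 2, rel=1e-12)
    assert g.michaelis_menten_rate(0.0, amylase) == 0.0
    assert g.michaelis_menten_rate(9 * km, amylase) == pytest.approx(0.9 * vmax, rel=1e-12)


def test_michaelis_menten_negative_handling(amylase, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="gutsim.solver"):
        assert g.michaelis_menten_rate(-1e-15, amylase) == 0.0
    assert any("clipped" in r.message for r in caplog.records)
    with pytest.raises(DomainError):
        g.michaelis_menten_rate(-1.0, amylase)


# -------------------------------------------------------------- model 1

def test_model1_matches_closed_form_curve(geometry, water, glucose):
    res = g.simulate_model1(50.0)
    k_a = absorption_rate_constant(geometry, water, glucose)
    ref = model1_closed_form(res.times, k_a)
    np.testing.assert_allclose(res.fraction_absorbed, ref, atol=0.01)
    assert res.fraction_absorbed[-1] == pytest.approx(0.859, abs=0.005)


def test_model1_one_hour_half_absorbed():
    res = g.simulate_model1(50.0, horizon=3600.0)
    assert res.fraction_absorbed[-1] == pytest.approx(0.479, abs=0.005)


def test_model1_viscous_meal_low_absorption():
    res = g.simulate_model1(50.0, fluid=g.FluidProperties(viscosity=0.2))
    assert res.fraction_absorbed[-1] == pytest.approx(0.056, abs=0.005)


def test_model1_conservation(geometry):
    res = g.simulate_model1(50.0)
    assert g.mass_balance_report(res).max_residual < 1e-6


def test_model1_zero_input_residuals():
    res = g.simulate_model1(0.0)
    np.testing.assert_array_equal(res.mass_balance_residuals(), 0.0)
    assert np.all(res.fraction_absorbed == 0.0)


def test_model1_absorbed_monotone_and_bounded():
    res = g.simulate_model1(50.0)
    assert np.all(np.diff(res.absorbed) >= -1e-9)
    assert np.all(np.diff(res.exited) >= -1e-9)
    assert np.all((res.fraction_absorbed >= 0) & (res.fraction_absorbed <= 1))


def test_model1_fraction_decreasing_in_viscosity():
    fracs = [
        g.simulate_model1(50.0, fluid=g.FluidProperties(viscosity=mu)).fraction_absorbed[-1]
        for mu in (1e-3, 1e-2, 1e-1, 1.0)
    ]
    assert all(a > b for a, b in zip(fracs, fracs[1:]))


def test_model1_scale_invariance():
    """Fraction absorbed is independent of meal mass and entry length."""
    base = g.simulate_model1(50.0).fraction_absorbed[-1]
    small = g.simulate_model1(5.0).fraction_absorbed[-1]
    moved = g.simulate_model1(50.0, l0=0.1).fraction_absorbed[-1]
    assert small == pytest.approx(base, rel=1e-9)
    assert moved == pytest.approx(base, rel=1e-6)


def test_model1_grid_halving_converged():
    coarse = g.simulate_model1(50.0, grid_spec=g.GridSpec(n_cells=250)).fraction_absorbed[-1]
    fine = g.simulate_model1(50.0, grid_spec=g.GridSpec(n_cells=500)).fraction_absorbed[-1]
    assert abs(fine - coarse) / fine < 0.005


def test_model1_kcal_rate_tracks_luminal_mass(geometry, water, glucose):
    res = g.simulate_model1(50.0)
    k_a = absorption_rate_constant(geometry, water, glucose)
    expected = k_a * res.luminal_glucose * 60.0 * 4.0
    np.testing.assert_allclose(res.absorbed_kcal_rate, expected, rtol=1e-12)


# -------------------------------------------------------------- model 2

def test_model2_matches_quadrature_curve(geometry, water, glucose, emptying_30min):
    res = g.simulate_model2(50.0, emptying_30min)
    k_a = absorption_rate_constant(geometry, water, glucose)
    ref = model2_quadrature(res.times, k_a, emptying_30min.gamma)
    np.testing.assert_allclose(res.fraction_absorbed, ref, atol=0.01)
    assert res.fraction_absorbed[-1] == pytest.approx(0.747, abs=0.005)


def test_model2_starts_empty(emptying_30min):
    res = g.simulate_model2(50.0, emptying_30min)
    assert res.fraction_absorbed[0] == 0.0
    assert res.stomach_glucose[0] == pytest.approx(50.0)
    assert res.luminal_glucose[0] == 0.0


def test_model2_instant_emptying_degenerates_to_bolus():
    fast = g.EmptyingParams(half_time=1.0)
    res2 = g.simulate_model2(50.0, fast)
    res1 = g.simulate_model1(50.0)
    assert res2.fraction_absorbed[-1] == pytest.approx(
        res1.fraction_absorbed[-1], rel=0.01
    )


def test_model2_conservation(emptying_30min):
    res = g.simulate_model2(50.0, emptying_30min)
    assert g.mass_balance_report(res).max_residual < 1e-6


def test_model2_scale_invariance(emptying_30min):
    a = g.simulate_model2(50.0, emptying_30min).fraction_absorbed[-1]
    b = g.simulate_model2(1.0, emptying_30min).fraction_absorbed[-1]
    assert a == pytest.approx(b, rel=1e-9)


# -------------------------------------------------------------- model 3

def test_model3_matches_characteristics_oracle(geometry, water, glucose,
                                               emptying_30min, amylase):
    res = g.simulate_model3(50.0, emptying_30min, amylase)
    k_a = absorption_rate_constant(geometry, water, glucose)
    checkpoints = np.array([3600.0, 7200.0, 10800.0])
    ref = model3_characteristics(checkpoints, amylase, k_a, emptying_30min.gamma, 50.0)
    got = np.interp(checkpoints, res.times, res.fraction_absorbed)
    np.testing.assert_allclose(got, ref, atol=0.02)


def test_model3_fast_hydrolysis_limit(emptying_30min):
    fast = g.KineticsParams.from_mM(2500.0, 9.0)
    res3 = g.simulate_model3(50.0, emptying_30min, fast)
    res2 = g.simulate_model2(50.0, emptying_30min)
    assert res3.fraction_absorbed[-1] == pytest.approx(
        res2.fraction_absorbed[-1], rel=0.02
    )


def test_model3_negligible_hydrolysis_absorbs_nothing(emptying_30min):
    slow = g.KineticsParams.from_mM(1e-9, 9.0)
    res = g.simulate_model3(50.0, emptying_30min, slow)
    assert res.fraction_absorbed[-1] < 1e-6
    # everything is still starch: in the stomach, the lumen, or exited
    total_starch = res.stomach_starch[-1] + res.luminal_starch[-1] + res.exited_starch[-1]
    assert total_starch == pytest.approx(50.0, rel=1e-5)


def test_model3_conservation(emptying_30min, amylase):
    res = g.simulate_model3(50.0, emptying_30min, amylase)
    assert g.mass_balance_report(res).max_residual < 1e-5


def test_model3_more_vmax_more_absorption(emptying_30min):
    fracs = [
        g.simulate_model3(
            50.0, g.EmptyingParams(half_time=1200.0),
            g.KineticsParams.from_mM(vm, 9.0),
        ).fraction_absorbed[-1]
        for vm in (4.0, 9.0, 16.0)
    ]
    assert fracs[0] < fracs[1] < fracs[2]


def test_model3_grid_halving_converged(emptying_30min, amylase):
    coarse = g.simulate_model3(50.0, emptying_30min, amylase,
                               grid_spec=g.GridSpec(n_cells=250)).fraction_absorbed[-1]
    fine = g.simulate_model3(50.0, emptying_30min, amylase,
                             grid_spec=g.GridSpec(n_cells=500)).fraction_absorbed[-1]
    assert abs(fine - coarse) / fine < 0.005


# ----------------------------------------------------------- bookkeeping

def test_mass_balance_report_grid_refinement(emptying_30min, amylase):
    """The conservation audit is an integrator-accuracy report: it stays
    tiny on both grids and does not blow up on the coarse one."""
    coarse = g.simulate_model3(50.0, emptying_30min, amylase,
                               grid_spec=g.GridSpec(n_cells=100))
    fine = g.simulate_model3(50.0, emptying_30min, amylase,
                             grid_spec=g.GridSpec(n_cells=500))
    assert g.mass_balance_report(coarse).max_residual < 1e-5
    assert g.mass_balance_report(fine).max_residual < 1e-5


def test_result_dataframe_roundtrip(emptying_30min):
    res = g.simulate_model2(50.0, emptying_30min)
    frame = res.to_dataframe()
    assert list(frame.columns) == [
        "time_s", "stomach_g", "luminal_g", "absorbed_g", "exited_g",
        "fraction_absorbed", "kcal_per_min",
    ]
    assert len(frame) == len(res.times)
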