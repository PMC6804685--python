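import dataclasses

import numpy as np
import pytest

from conftest import cd_toy_closed_form

from fiscalfood.cge import (
    Closure,
    advance,
    calibrate,
    dynamic_calibrate,
    initial_state,
    run_forward,
    solve_period,
)
from fiscalfood.cge.calibrate import average_tariff, recovered_tariff_rates
from fiscalfood.sam import SocialAccountingMatrix


# --- calibration -------------------------------------------------------------


def test_benchmark_replication(params, base_state, base_eq):
    """Solving the calibrated model with base policy reproduces the SAM."""
    assert np.max(np.abs(base_eq.pd_ - 1.0)) <= 1e-8
    assert np.max(np.abs(base_eq.wf - 1.0)) <= 1e-8
    assert abs(base_eq.exr - 1.0) <= 1e-8
    assert np.max(np.abs(base_eq.qa / params.qa0 - 1.0)) <= 1e-8
    np.testing.assert_allclose(base_eq.x, params.x0, rtol=1e-8)
    np.testing.assert_allclose(base_eq.m, params.m0, rtol=1e-8)
    assert base_eq.gdp_real == pytest.approx(params.gdp_real0, rel=1e-8)


def test_recovered_average_tariff(params):
    assert average_tariff(params) == pytest.approx(0.016, abs=0.0005)
    rates = recovered_tariff_rates(params)
    bev = params.sectors.index("beverages")
    assert rates[bev] == pytest.approx(0.227, abs=0.0005)


def test_doubled_sam_same_real_calibration(coarse_sam, bundle):
    """Doubling all SAM flows doubles nominal scale, leaves structure intact."""
    doubled = SocialAccountingMatrix(list(coarse_sam.labels), 2.0 * coarse_sam.flows)
    p2 = calibrate(doubled, bundle.demand)
    p1 = calibrate(coarse_sam, bundle.demand)
    np.testing.assert_allclose(p2.tm0, p1.tm0, atol=1e-12)
    np.testing.assert_allclose(p2.mps, p1.mps, atol=1e-12)
    np.testing.assert_allclose(p2.qa0, 2.0 * p1.qa0, rtol=1e-12)
    eq = solve_period(p2, initial_state(p2), p2.tm0)
    assert np.max(np.abs(eq.pd_ - 1.0)) <= 1e-8
    assert eq.gdp_real == pytest.approx(2.0 * p1.gdp_real0, rel=1e-8)


def test_zero_value_added_rejected(coarse_sam, bundle):
    flows = coarse_sam.flows.copy()
    fac_rows = [i for i, lab in enumerate(coarse_sam.labels) if lab.startswith("fac.")]
    act_col = coarse_sam.labels.index("act.beverages")
    flows[fac_rows, act_col] = 0.0
    broken = SocialAccountingMatrix(list(coarse_sam.labels), flows)
    with pytest.raises(Exception):
        calibrate(broken, bundle.demand)


# --- within-period solve -----------------------------------------------------


def test_tariff_increase_weakly_reduces_imports(params, base_state, base_eq):
    tm = params.tm0.copy()
    bev = params.sectors.index("beverages")
    tm[bev] += 0.10
    eq = solve_period(params, base_state, tm, guess=base_eq.guess)
    assert eq.m[bev] <= base_eq.m[bev]
    assert abs(eq.walras) <= 1e-8


def test_tariff_elimination_weakly_increases_imports(params, base_state, base_eq):
    eq = solve_period(params, base_state, np.zeros(params.n_c), guess=base_eq.guess)
    assert eq.m.sum() >= base_eq.m.sum()


def test_walras_residual_under_shocks(params, base_state, base_eq):
    for rate in (0.1, 0.3):
        tm = np.full(params.n_c, rate)
        eq = solve_period(params, base_state, tm, guess=base_eq.guess)
        assert abs(eq.walras) <= 1e-8
        assert eq.resid_max <= 1e-9


def test_price_homogeneity_in_numeraire(params, base_state, base_eq):
    """Scaling the CPI target scales nominal variables, leaves real untouched."""
    lam = 1.8
    state = base_state.copy()
    state.cpi = lam
    eq = solve_period(params, state, params.tm0)
    assert eq.gdp_nominal == pytest.approx(lam * base_eq.gdp_nominal, rel=1e-10)
    np.testing.assert_allclose(eq.wf, lam * base_eq.wf, rtol=1e-10)
    assert eq.exr == pytest.approx(lam * base_eq.exr, rel=1e-10)
    assert eq.gdp_real == pytest.approx(base_eq.gdp_real, rel=1e-10)
    np.testing.assert_allclose(eq.qa, base_eq.qa, rtol=1e-10)
    np.testing.assert_allclose(eq.x, base_eq.x, rtol=1e-9)


def test_negative_tariffs_rejected(params, base_state):
    with pytest.raises(ValueError):
        solve_period(params, base_state, np.full(params.n_c, -0.1))


# --- Cobb-Douglas analytic oracle -------------------------------------------


def test_cobb_douglas_toy_matches_closed_form(cd_toy):
    params, prim = cd_toy
    state = initial_state(params)
    # benchmark first
    eq0 = solve_period(params, state, params.tm0)
    assert np.max(np.abs(eq0.pd_ - 1.0)) <= 1e-8
    # 10% labour-supply expansion
    state = state.copy()
    lab_ix = params.factors.index("labour")
    state.fs[lab_ix] *= 1.1
    eq = solve_period(params, state, params.tm0, guess=eq0.guess)
    oracle = cd_toy_closed_form(prim, prim["labour0"] * 1.1, prim["capital0"])
    assert eq.wf[lab_ix] == pytest.approx(oracle["w"], rel=1e-8)
    assert eq.wf[params.capital_factor] == pytest.approx(oracle["r"], rel=1e-8)
    np.testing.assert_allclose(eq.pd_, oracle["prices"], rtol=1e-8)
    np.testing.assert_allclose(eq.qq, oracle["quantities"], rtol=1e-8)
    assert abs(eq.walras) <= 1e-10


# --- dynamics ----------------------------------------------------------------


def test_capital_conservation_without_investment(params, base_state, base_eq):
    eq = dataclasses.replace(base_eq, qinv=np.zeros(params.n_c))
    new = advance(base_state, eq, params, depreciation=0.0)
    assert new.capital == base_state.capital
    assert new.year == base_state.year + 1


def test_full_depreciation_boundary(params, base_state, base_eq):
    eq = dataclasses.replace(base_eq, qinv=np.zeros(params.n_c))
    new = advance(base_state, eq, params, depreciation=1.0)
    assert new.capital == 0.0


def test_capital_update_rule(params, base_state, base_eq):
    new = advance(base_state, base_eq, params, depreciation=0.05)
    expected = 0.95 * base_state.capital + float(base_eq.qinv.sum())
    assert new.capital == pytest.approx(expected, rel=1e-12)


def test_null_growth_calibration_flat_path(params, base_state):
    trends, path = dynamic_calibrate(
        params, base_state, [2016, 2017, 2018], real_target=0.0, nominal_target=0.0
    )
    base = solve_period(params, base_state, params.tm0)
    for eq in path:
        assert eq.gdp_real == pytest.approx(base.gdp_real, rel=1e-6)
        assert eq.gdp_nominal == pytest.approx(base.gdp_nominal, rel=1e-6)


def test_planted_trend_recovery(params, base_state):
    """Recover planted productivity factors from the GDP path they generate."""
    years = [2016, 2017, 2018]
    planted = {2016: 1.012, 2017: 1.035, 2018: 1.051}
    cpis = {y: 1.0 for y in years}
    from fiscalfood.cge.dynamics import GrowthTrends

    path = run_forward(params, base_state, years, GrowthTrends(tfp=planted, cpi=cpis))
    levels = {y: eq.gdp_real for y, eq in zip(years, path)}
    recovered, _ = dynamic_calibrate(params, base_state, years, real_levels=levels)
    for y in years:
        assert recovered.tfp[y] == pytest.approx(planted[y], rel=1e-8)


def test_growth_calibration_hits_both_targets(engine, trends):
    """Counterfactual growth equals 3.9% real / 6.2% nominal every year to 1e-6."""
    params = engine.params
    years = list(range(2016, 2036))
    count = engine.counterfactual("bau", years)
    prev_r, prev_n = engine.base_eq.gdp_real, engine.base_eq.gdp_nominal
    for y in years:
        eq = count.eqs[y]
        assert eq.gdp_real / prev_r - 1.0 == pytest.approx(0.039, abs=1e-6)
        assert eq.gdp_nominal / prev_n - 1.0 == pytest.approx(0.062, abs=1e-6)
        assert abs(eq.walras) <= 1e-8
        prev_r, prev_n = eq.gdp_real, eq.gdp_nominal


# --- efficiency closure -------------------------------------------------------


def test_efficiency_closure_invariants(params, base_state, base_eq, bundle):
    tm = np.where([s in bundle.smap.food for s in params.sectors], 0.3, 0.0)
    closure = Closure(
        mode="efficiency",
        gov_real_target=base_eq.gov_real,
        cons_real_target=base_eq.cons_real,
    )
    eq = solve_period(params, base_state, tm, closure, guess=base_eq.guess)
    assert eq.cons_real == pytest.approx(base_eq.cons_real, rel=1e-8)
    assert eq.gov_real == pytest.approx(base_eq.gov_real, rel=1e-8)
    # real trade balance fixed by the external closure
    nx0 = float(params.pwe @ base_eq.e - params.pwm @ base_eq.m)
    nx1 = float(params.pwe @ eq.e - params.pwm @ eq.m)
    assert nx1 == pytest.approx(nx0, abs=1e-6 * params.gdp_real0)
    assert eq.savadj != 1.0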