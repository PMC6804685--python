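import numpy as np
import pytest

from fiscalfood.scenarios import (
    ScenarioError,
    ScenarioSpec,
    SimulationEngine,
    cost_effectiveness,
    run_scenario,
)

YEARS = list(range(2016, 2036))


@pytest.fixture(scope="module")
def null_result(engine):
    spec = ScenarioSpec(name="null", counterfactual="bau", intervention="none")
    return run_scenario(spec, engine, modes=("policy", "efficiency", "pathway"))


@pytest.fixture(scope="module")
def elim_all_result(engine):
    spec = ScenarioSpec(name="elim_all", counterfactual="bau", intervention="eliminate_all")
    return run_scenario(spec, engine, modes=("policy", "efficiency", "pathway"))


@pytest.fixture(scope="module")
def food30_result(engine):
    spec = ScenarioSpec(name="food30", counterfactual="nitd", intervention="uniform_food")
    return run_scenario(spec, engine, modes=("policy", "efficiency"))


def test_spec_validation():
    with pytest.raises(ScenarioError):
        ScenarioSpec(counterfactual="other")
    with pytest.raises(ScenarioError):
        ScenarioSpec(intervention="sector")  # needs a sector name
    with pytest.raises(ScenarioError):
        ScenarioSpec(rate=-0.1)


def test_tariff_templates(engine):
    food = np.array([s in engine.bundle.smap.food for s in engine.params.sectors])
    tm = engine.tariffs("uniform_food", rate=0.3)
    assert np.all(tm[food] == 0.3) and np.all(tm[~food] == 0.0)
    tm = engine.tariffs("eliminate_food")
    assert np.all(tm[food] == 0.0)
    np.testing.assert_array_equal(tm[~food], engine.params.tm0[~food])
    tm = engine.tariffs("sector", sector="beverages", rate=0.3)
    assert tm[engine.params.sectors.index("beverages")] == 0.3
    assert tm.sum() == pytest.approx(0.3)
    with pytest.raises(ScenarioError):
        engine.tariffs("sector", sector="nope")


def test_null_scenario_all_zero_deltas(null_result):
    s = null_result.summary
    scale = null_result.count.gdp_real(2035)
    assert abs(s["real_gdp_policy_cum"]) <= 1e-6 * scale
    assert abs(s["real_gdp_efficiency_cum"]) <= 1e-6 * scale
    assert abs(s["real_gdp_pathway_cum"]) <= 1e-6 * scale
    for key in ("sfa_share_longrun_pct", "mufa_share_longrun_pct", "pufa_share_longrun_pct",
                "chol_longrun_pct", "incident_cases_cum", "premature_deaths_cum",
                "person_years_cum", "workforce_person_years_cum", "ghg_longrun_mt"):
        assert abs(s[key]) <= 1e-6, key


def test_same_seed_runs_bit_identical(bundle):
    """Two fresh engines, same fixture: identical scenario output."""
    spec = ScenarioSpec(name="det", counterfactual="bau",
                        intervention="eliminate_food", start=2016, end=2018)
    r1 = run_scenario(spec, SimulationEngine(bundle), modes=("policy",))
    r2 = run_scenario(spec, SimulationEngine(bundle), modes=("policy",))
    for key, v in r1.summary.items():
        if v is None:
            assert r2.summary[key] is None
        else:
            assert r2.summary[key] == v, key


def test_twin_run_consistency(engine, elim_all_result):
    """eliminate-all vs BaU equals the NITD-minus-BaU paths assembled separately."""
    nitd = engine.counterfactual("nitd", YEARS)
    bau = engine.counterfactual("bau", YEARS)
    for y in (2016, 2025, 2035):
        expected = nitd.gdp_real(y) - bau.gdp_real(y)
        got = elim_all_result.policy.gdp_real(y) - elim_all_result.count.gdp_real(y)
        assert got == pytest.approx(expected, abs=1e-9 * bau.gdp_real(y))
        np.testing.assert_allclose(elim_all_result.policy.pop[y], nitd.pop[y], rtol=1e-12)


def test_food_tariffs_cut_food_imports(engine, food30_result):
    food = np.array([s in engine.bundle.smap.food for s in engine.params.sectors])
    for y in (2016, 2025, 2035):
        pol = food30_result.policy.eqs[y].m[food].sum()
        cnt = food30_result.count.eqs[y].m[food].sum()
        assert pol < cnt


def test_efficiency_run_pins_consumption(engine, food30_result):
    spec = ScenarioSpec(counterfactual="nitd", intervention="uniform_food")
    eff = engine.run(engine.policy_tariffs(spec), YEARS,
                     reference=food30_result.count, mode="efficiency")
    for y in YEARS:
        assert eff.eqs[y].cons_real == pytest.approx(
            food30_result.count.eqs[y].cons_real, rel=1e-8
        )
        assert eff.eqs[y].gov_real == pytest.approx(
            food30_result.count.eqs[y].gov_real, rel=1e-8
        )


def test_uniform_tariff_efficiency_loss(food30_result):
    """Deadweight-loss sign oracle: distortionary tariffs lose efficiency."""
    assert food30_result.summary["real_gdp_efficiency_cum"] <= 0.0


def test_tariff_elimination_efficiency_gain(elim_all_result):
    assert elim_all_result.summary["real_gdp_efficiency_cum"] >= 0.0


def test_policy_deltas_track_health_chain(elim_all_result):
    s = elim_all_result.summary
    # liberalization worsens health on this fixture: more cases, fewer person-years
    assert s["incident_cases_cum"] > 0
    assert s["premature_deaths_cum"] > 0
    assert s["person_years_cum"] < 0
    assert s["person_years_per_100k"] < 0


def test_pathway_null_shock_zero(engine, null_result):
    assert abs(null_result.summary["real_gdp_pathway_cum"]) <= 1e-6 * null_result.count.gdp_real(2035)


def test_pathway_linear_and_signed_in_small_ls_shocks(engine):
    """Health-pathway valuation responds linearly (to first order) to labour shocks."""
    years = YEARS[:4]
    count = engine.counterfactual("bau", years)
    base_ls = engine.ls0

    def pathway_delta(eps):
        shock = {y: eps * base_ls for y in years}
        zero_hc = ({y: np.zeros(engine.params.n_h) for y in years}, {y: 0.0 for y in years})
        run = engine.run(engine.params.tm0.copy(), years, reference=count,
                         mode="pathway", exog_ls=shock, exog_hc=zero_hc)
        return sum(run.gdp_real(y) - count.gdp_real(y) for y in years)

    d1 = pathway_delta(1e-3)
    d2 = pathway_delta(2e-3)
    assert d1 > 0  # more labour, more output
    assert d2 / d1 == pytest.approx(2.0, rel=0.05)


def test_scenario_composition_residual_is_small(engine):
    """Food + non-food elimination approximately decomposes total elimination."""
    years = list(range(2016, 2020))
    kwargs = dict(counterfactual="bau", start=2016, end=2019)
    total = run_scenario(ScenarioSpec(intervention="eliminate_all", **kwargs), engine, modes=("policy",))
    food = run_scenario(ScenarioSpec(intervention="eliminate_food", **kwargs), engine, modes=("policy",))
    nonfood = run_scenario(ScenarioSpec(intervention="eliminate_nonfood", **kwargs), engine, modes=("policy",))
    t = total.summary["real_gdp_policy_cum"]
    parts = food.summary["real_gdp_policy_cum"] + nonfood.summary["real_gdp_policy_cum"]
    residual = abs(t - parts)
    assert residual <= 0.5 * abs(t)  # interaction terms exist but are second order


def test_elimination_vs_nitd_rejected(engine):
    spec = ScenarioSpec(counterfactual="nitd", intervention="eliminate_food")
    with pytest.raises(ScenarioError):
        engine.policy_tariffs(spec)


# --- cost effectiveness -------------------------------------------------------


def test_cost_effectiveness_zero_loss():
    rep = cost_effectiveness(0.0, 1000.0)
    assert rep.cost_per_person_year_rounded == 0.0


def test_cost_effectiveness_requires_positive_person_years():
    with pytest.raises(ScenarioError):
        cost_effectiveness(1e9, 0.0)


def test_cost_effectiveness_carbon_adjustment():
    rep = cost_effectiveness(1e9, 10_000.0, ghg_mt=1.0, carbon_price=100.0, rounding=1e4)
    assert rep.ghg_value_usd == pytest.approx(1e8)
    assert rep.ghg_adjusted_cost_rounded == pytest.approx(90_000.0)
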