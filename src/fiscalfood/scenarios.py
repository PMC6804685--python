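"""Scenario orchestration: counterfactual/policy run pairs and indicators.

A scenario couples the annual loop — equilibrium solve, food demand, fatty-acid
intakes, biomarker shift, clinical rates and levels, demographic projection
with excess-mortality feedback, time losses / labour supply / health costs —
for a counterfactual and a policy tariff schedule, then assembles
policy-minus-counterfactual indicator deltas, efficiency and health-pathway
decompositions and the cost-effectiveness report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clinical, demography, feedbacks, luc, nutrition
from .cge import (
    Closure,
    EconomyState,
    Equilibrium,
    GrowthTrends,
    advance,
    calibrate,
    dynamic_calibrate,
    initial_state,
    solve_period,
)
from .fixtures import FixtureBundle
from .sam import aggregate

INTERVENTIONS = (
    "none",
    "eliminate_food",
    "eliminate_nonfood",
    "eliminate_all",
    "uniform_food",
    "uniform_all",
    "sector",
)


class ScenarioError(ValueError):
    pass


@dataclass
class ScenarioSpec:
    """One policy experiment.

    counterfactual : 'bau' (calibrated tariffs) or 'nitd' (all tariffs zero)
    intervention   : one of the tariff templates above
    sector         : target sector for the 'sector' template
    rate           : uniform/sector tariff rate (default 30%)
    """

    name: str = "scenario"
    counterfactual: str = "bau"
    intervention: str = "none"
    sector: str | None = None
    rate: float = 0.30
    start: int = 2016
    end: int = 2035

    def __post_init__(self) -> None:
        if self.counterfactual not in ("bau", "nitd"):
            raise ScenarioError(f"unknown counterfactual {self.counterfactual!r}")
        if self.intervention not in INTERVENTIONS:
            raise ScenarioError(f"unknown intervention {self.intervention!r}")
        if self.intervention == "sector" and not self.sector:
            raise ScenarioError("sector intervention needs a sector name")
        if self.rate < 0:
            raise ScenarioError("tariff rate must be non-negative")

    @property
    def years(self) -> list[int]:
        return list(range(self.start, self.end + 1))

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScenarioSpec":
        known = {k: cfg[k] for k in
                 ("name", "counterfactual", "intervention", "sector", "rate", "start", "end")
                 if k in cfg}
        return cls(**known)


@dataclass
class RunPath:
    """Per-year outputs of one simulation run."""

    years: list[int]
    eqs: dict[int, Equilibrium] = field(default_factory=dict)
    intake: dict[int, np.ndarray] = field(default_factory=dict)     # (H, 3)
    chol_mean: dict[int, np.ndarray] = field(default_factory=dict)  # (H,)
    dists: dict[int, list] = field(default_factory=dict)
    levels: dict[int, np.ndarray] = field(default_factory=dict)     # (H, G, A, I)
    pop: dict[int, np.ndarray] = field(default_factory=dict)        # (H, G, A)
    ls: dict[int, np.ndarray] = field(default_factory=dict)         # (H, 2)
    hc_total: dict[int, np.ndarray] = field(default_factory=dict)   # (H, 2)
    hc_real_private: dict[int, np.ndarray] = field(default_factory=dict)
    hc_real_public: dict[int, float] = field(default_factory=dict)
    land: dict[int, luc.LandAllocation] = field(default_factory=dict)
    ghg: dict[int, float] = field(default_factory=dict)             # cumulative level
    excess: dict[int, np.ndarray] = field(default_factory=dict)     # (H, G, A, 2)
    tu_patient: dict[int, np.ndarray] = field(default_factory=dict)
    tu_care_work: dict[int, np.ndarray] = field(default_factory=dict)

    def gdp_real(self, year: int) -> float:
        return self.eqs[year].gdp_real


class SimulationEngine:
    """Calibrated model stack bound to one fixture bundle."""

    def __init__(self, bundle: FixtureBundle, elasticities: dict | None = None):
        self.bundle = bundle
        self.coarse = aggregate(bundle.sam, bundle.smap)
        self.params = calibrate(self.coarse, bundle.demand, elasticities)
        self.households = [f"hh.{h}" for h in self.params.households]
        self.unsk = self.params.factors.index("labour_unskilled")
        self.sk = self.params.factors.index("labour_skilled")
        self.he = bundle.healthecon
        self.base_year = 2015

        pop0 = bundle.demog.initial.pop
        self.ls0 = feedbacks.labour_supply(pop0, self.he)
        self.base_state = initial_state(self.params, year=self.base_year)
        self.base_eq = solve_period(self.params, self.base_state, self.params.tm0)

        # baseline intake shares per household from benchmark consumption
        self.intake0 = np.array(
            [
                nutrition.intake_shares(self.base_eq.x[:, h], bundle.nutrients[hh])
                for h, hh in enumerate(self.params.households)
            ]
        )
        # base-year clinical levels (used to pad the cost-lag history)
        self.levels0 = self._clinical_levels(
            {h: bundle.biomarkers[h] for h in self.params.households}, pop0
        )
        self._ptrans = demography.calibrate_transitions(
            bundle.demog.initial, bundle.demog.targets, bundle.demog.rates_path
        )
        self._trends: GrowthTrends | None = None
        self._count_cache: dict[str, RunPath] = {}

    # -- helpers -----------------------------------------------------------

    def tariffs(self, spec_kind: str, sector: str | None = None, rate: float = 0.3) -> np.ndarray:
        """Tariff vector for a template applied on top of the counterfactual."""
        food = [s in self.bundle.smap.food for s in self.params.sectors]
        tm = self.params.tm0.copy()
        if spec_kind == "eliminate_food":
            tm[np.array(food)] = 0.0
        elif spec_kind == "eliminate_nonfood":
            tm[~np.array(food)] = 0.0
        elif spec_kind == "eliminate_all":
            tm[:] = 0.0
        elif spec_kind == "uniform_food":
            tm = np.zeros_like(tm)
            tm[np.array(food)] = rate
        elif spec_kind == "uniform_all":
            tm = np.full_like(tm, rate)
        elif spec_kind == "sector":
            tm = np.zeros_like(tm)
            if sector not in self.params.sectors:
                raise ScenarioError(f"unknown sector {sector!r}")
            tm[self.params.sectors.index(sector)] = rate
        elif spec_kind != "none":
            raise ScenarioError(f"unknown template {spec_kind!r}")
        return tm

    def counterfactual_tariffs(self, kind: str) -> np.ndarray:
        return self.params.tm0.copy() if kind == "bau" else np.zeros(self.params.n_c)

    def policy_tariffs(self, spec: ScenarioSpec) -> np.ndarray:
        if spec.intervention == "none":
            return self.counterfactual_tariffs(spec.counterfactual)
        if spec.counterfactual == "nitd" and spec.intervention.startswith("eliminate"):
            raise ScenarioError("elimination scenarios are measured against BaU")
        return self.tariffs(spec.intervention, spec.sector, spec.rate)

    def _labour_factor_supplies(self, ls: np.ndarray) -> dict[int, float]:
        ls0 = self.ls0.sum(axis=0)
        fs0 = self.params.fs0
        return {
            self.unsk: fs0[self.unsk] * ls[:, 0].sum() / ls0[0],
            self.sk: fs0[self.sk] * ls[:, 1].sum() / ls0[1],
        }

    def bau_labour_path(self, years: list[int]) -> tuple[dict, dict[int, np.ndarray], dict[int, np.ndarray]]:
        """Business-as-usual labour supplies per year (no health deltas)."""
        state = self.bundle.demog.initial.copy()
        path, ls_path, pop_path = {}, {}, {}
        for t_ix, year in enumerate(years):
            ls = feedbacks.labour_supply(state.pop, self.he)
            ls_path[year] = ls
            path[year] = self._labour_factor_supplies(ls)
            rates = self.bundle.demog.rates_path[t_ix]
            cal = demography.VitalRates(
                rates.sexratio, rates.asfr, rates.mortality, rates.migration, self._ptrans[t_ix]
            )
            state = demography.project_year(state, cal)
            pop_path[year] = state.pop.copy()
        return path, ls_path, pop_path

    def trends(self, years: list[int] | None = None) -> GrowthTrends:
        if self._trends is None:
            years = years or list(range(2016, 2036))
            labour_path, _, _ = self.bau_labour_path(years)
            self._trends, _ = dynamic_calibrate(
                self.params, self.base_state, years, labour_path
            )
        return self._trends

    def _clinical_levels(self, dists: dict, pop: np.ndarray) -> np.ndarray:
        out = np.zeros((self.params.n_h, 2, demography.N_AGES, len(clinical.ILLNESSES)))
        for h, hh in enumerate(self.params.households):
            r = clinical.rates(self.bundle.lookup, dists[hh], hh)
            out[h] = clinical.levels(r, dists[hh], pop[h], hh).levels
        return out

    # -- core annual loop --------------------------------------------------

    def run(
        self,
        tm: np.ndarray,
        years: list[int],
        reference: RunPath | None = None,
        mode: str = "policy",
        exog_ls: dict[int, np.ndarray] | None = None,
        exog_hc: tuple[dict[int, np.ndarray], dict[int, float]] | None = None,
    ) -> RunPath:
        """Execute the annual loop under one tariff schedule.

        mode 'policy' runs the full health chain (with deltas measured against
        ``reference`` when given); 'efficiency' and 'pathway' run the economy
        only, with the closure/exogenous paths the decompositions require.
        """
        if mode not in ("policy", "efficiency", "pathway"):
            raise ScenarioError(f"unknown run mode {mode!r}")
        if mode in ("efficiency", "pathway") and reference is None:
            raise ScenarioError(f"{mode} run needs a counterfactual reference")
        trends = self.trends(years)
        params, bundle = self.params, self.bundle
        out = RunPath(years=list(years))

        econ = self.base_state.copy()
        eq_prev = self.base_eq
        pop_state = bundle.demog.initial.copy()
        dists = {h: bundle.biomarkers[h] for h in params.households}
        intake_prev = self.intake0.copy()
        chol_mean = np.array([dists[h].mean for h in params.households])
        case_hist: dict[int, np.ndarray] = {}
        nf_ix = [clinical.ILLNESSES.index(i) for i in clinical.NONFATAL]
        base_cases = self.levels0[:, :, :, nf_ix].sum(axis=(1, 2))
        for back in range(1, feedbacks.N_LAGS + 1):
            case_hist[years[0] - back] = base_cases
        land_prev: luc.LandAllocation | None = None
        ghg_level = 0.0
        ls_next = self.ls0.copy()
        hcp_real_next = np.zeros(params.n_h)
        hcg_real_next = 0.0

        for t_ix, year in enumerate(years):
            # --- economy ---
            econ = advance(econ, eq_prev, params)
            econ.year = year
            econ.tfp = trends.tfp[year]
            econ.cpi = trends.cpi[year]
            if mode == "efficiency":
                ls_t = reference.ls[year]
                closure = Closure(
                    mode="efficiency",
                    gov_real_target=reference.eqs[year].gov_real,
                    cons_real_target=reference.eqs[year].cons_real,
                )
            elif mode == "pathway":
                ls_t = reference.ls[year] + (exog_ls[year] if exog_ls else 0.0)
                closure = Closure(
                    mode="fixed_gov",
                    gov_real_target=reference.eqs[year].gov_real,
                    hcp_real=exog_hc[0][year] if exog_hc else None,
                    hcg_real=exog_hc[1][year] if exog_hc else 0.0,
                )
            else:
                ls_t = ls_next
                if reference is None:
                    closure = Closure(mode="ratio")
                else:
                    closure = Closure(
                        mode="fixed_gov",
                        gov_real_target=reference.eqs[year].gov_real,
                        hcp_real=hcp_real_next.copy(),
                        hcg_real=hcg_real_next,
                    )
            for f, supply in self._labour_factor_supplies(ls_t).items():
                econ.fs[f] = supply
            eq = solve_period(params, econ, tm, closure, guess=eq_prev.guess)
            out.eqs[year] = eq
            out.ls[year] = ls_t.copy()

            # --- land / emissions ---
            land = luc.LandAllocation(
                [params.sectors[a] for a in params.ag_activities], eq.land_allocation(params)
            )
            if land_prev is not None:
                flows = luc.transitions(land_prev, land)
                ghg_level += luc.ghg_delta(flows, bundle.emissions)
            out.land[year] = land
            out.ghg[year] = ghg_level
            land_prev = land
            eq_prev = eq

            if mode in ("efficiency", "pathway"):
                continue

            # --- nutrition and biomarker shift ---
            intake = np.array(
                [
                    nutrition.intake_shares(eq.x[:, h], bundle.nutrients[hh])
                    for h, hh in enumerate(params.households)
                ]
            )
            d_intake = intake - intake_prev
            for h, hh in enumerate(params.households):
                dchol = nutrition.cholesterol_delta(
                    d_intake[h, 0], d_intake[h, 1], d_intake[h, 2],
                    tuple(intake[h]), bundle.chol_response,
                )
                dists[hh] = nutrition.shift_distribution(dists[hh], dchol)
            intake_prev = intake
            chol_mean = np.array([dists[h].mean for h in params.households])
            out.intake[year] = intake
            out.chol_mean[year] = chol_mean
            out.dists[year] = [dists[h] for h in params.households]

            # --- clinical rates, mortality feedback, demography ---
            fat_ix = [clinical.ILLNESSES.index(i) for i in clinical.FATAL]
            strat_rates = {
                hh: clinical.rates(bundle.lookup, dists[hh], hh) for hh in params.households
            }
            excess = np.stack(
                [
                    demography.excess_mortality(
                        dists[hh].freq, strat_rates[hh][:, :, :, fat_ix]
                    )
                    for hh in params.households
                ]
            )  # (H, G, A, 2)
            base_rates = bundle.demog.rates_path[t_ix]
            if reference is not None:
                mu = demography.apply_excess_feedback(
                    base_rates.mortality, excess, reference.excess[year]
                )
            else:
                mu = base_rates.mortality
            vr = demography.VitalRates(
                base_rates.sexratio, base_rates.asfr, mu, base_rates.migration,
                self._ptrans[t_ix],
            )
            pop_state = demography.project_year(pop_state, vr)
            out.pop[year] = pop_state.pop.copy()
            out.excess[year] = excess

            lev = np.zeros_like(self.levels0)
            for h, hh in enumerate(params.households):
                lev[h] = clinical.levels(strat_rates[hh], dists[hh], pop_state.pop[h], hh).levels
            out.levels[year] = lev

            # --- feedbacks (applied to next year's economy) ---
            tl = feedbacks.time_losses(lev, params.households, self.he)
            out.tu_patient[year] = tl.patient_work
            out.tu_care_work[year] = tl.caregiver_work
            case_hist[year] = lev[:, :, :, nf_ix].sum(axis=(1, 2))
            hc = feedbacks.health_costs(case_hist, year, self.he, eq.gdpdef)
            out.hc_total[year] = hc.total
            out.hc_real_private[year] = hc.private.sum(axis=1) / eq.gdpdef
            out.hc_real_public[year] = float(hc.public.sum()) / eq.gdpdef

            if reference is not None:
                d_pat = tl.patient_work - reference.tu_patient[year]
                d_care = tl.caregiver_work - reference.tu_care_work[year]
                ls_next = feedbacks.labour_supply(
                    pop_state.pop, self.he, patient_delta=d_pat, caregiver_delta=d_care
                )
                hcp_real_next = out.hc_real_private[year] - reference.hc_real_private[year]
                hcg_real_next = out.hc_real_public[year] - reference.hc_real_public[year]
            else:
                ls_next = feedbacks.labour_supply(pop_state.pop, self.he)
        return out

    def counterfactual(self, kind: str, years: list[int]) -> RunPath:
        """Counterfactual run path (cached).

        The business-as-usual counterfactual defines the growth path; the
        no-tariff-distortion counterfactual is itself executed as a policy run
        against business-as-usual, so that "eliminate all tariffs vs BaU" and
        the NITD baseline are the same simulation (twin-run consistency).
        """
        key = f"{kind}:{years[0]}-{years[-1]}"
        if key not in self._count_cache:
            if kind == "bau":
                run = self.run(self.params.tm0.copy(), years, reference=None, mode="policy")
            else:
                bau = self.counterfactual("bau", years)
                run = self.run(np.zeros(self.params.n_c), years, reference=bau, mode="policy")
            self._count_cache[key] = run
        return self._count_cache[key]


@dataclass
class ScenarioResult:
    """Policy-vs-counterfactual deltas for the core indicator set."""

    spec: ScenarioSpec
    summary: dict
    per_year: pd.DataFrame
    policy: RunPath = field(repr=False, default=None)
    count: RunPath = field(repr=False, default=None)


def run_scenario(
    spec: ScenarioSpec,
    engine_or_bundle,
    modes: tuple[str, ...] = ("policy", "efficiency", "pathway"),
) -> ScenarioResult:
    """Execute a full scenario: counterfactual, policy, and decompositions."""
    engine = (
        engine_or_bundle
        if isinstance(engine_or_bundle, SimulationEngine)
        else SimulationEngine(engine_or_bundle)
    )
    years = spec.years
    count = engine.counterfactual(spec.counterfactual, years)
    tm_pol = engine.policy_tariffs(spec)
    policy = engine.run(tm_pol, years, reference=count, mode="policy")

    eff_delta = path_delta = None
    if "efficiency" in modes:
        eff = engine.run(tm_pol, years, reference=count, mode="efficiency")
        eff_delta = sum(eff.gdp_real(y) - count.gdp_real(y) for y in years)
    if "pathway" in modes:
        d_ls = {y: policy.ls[y] - count.ls[y] for y in years}
        d_hcp = {
            y: policy.hc_real_private[y] - count.hc_real_private[y] for y in years
        }
        d_hcg = {y: policy.hc_real_public[y] - count.hc_real_public[y] for y in years}
        # deltas are applied with a one-year lag in the policy run; mirror that
        lagged_ls = {y: d_ls.get(y - 1, np.zeros_like(d_ls[years[0]])) for y in years}
        lagged_hcp = {y: d_hcp.get(y - 1, np.zeros_like(d_hcp[years[0]])) for y in years}
        lagged_hcg = {y: d_hcg.get(y - 1, 0.0) for y in years}
        pw = engine.run(
            engine.counterfactual_tariffs(spec.counterfactual),
            years,
            reference=count,
            mode="pathway",
            exog_ls=lagged_ls,
            exog_hc=(lagged_hcp, lagged_hcg),
        )
        path_delta = sum(pw.gdp_real(y) - count.gdp_real(y) for y in years)

    T = years[-1]
    nf_ix = [clinical.ILLNESSES.index(i) for i in clinical.NONFATAL]
    fat_ix = [clinical.ILLNESSES.index(i) for i in clinical.FATAL]

    def cum_levels(path: RunPath, ix):
        return sum(path.levels[y][:, :, :, ix].sum() for y in years)

    cases_d = cum_levels(policy, nf_ix) - cum_levels(count, nf_ix)
    deaths_d = cum_levels(policy, fat_ix) - cum_levels(count, fat_ix)
    py_count = sum(count.pop[y].sum() for y in years)
    py_delta = sum(policy.pop[y].sum() - count.pop[y].sum() for y in years)
    wf_count = sum(count.ls[y].sum() for y in years)
    wf_delta = sum(policy.ls[y].sum() - count.ls[y].sum() for y in years)
    gdp_delta = sum(policy.gdp_real(y) - count.gdp_real(y) for y in years)

    def rel(a, b):
        return (a / b - 1.0) * 100.0

    summary = {
        "real_gdp_policy_cum": gdp_delta,
        "real_gdp_efficiency_cum": eff_delta,
        "real_gdp_pathway_cum": path_delta,
        "sfa_share_longrun_pct": rel(policy.intake[T][:, 0].mean(), count.intake[T][:, 0].mean()),
        "mufa_share_longrun_pct": rel(policy.intake[T][:, 1].mean(), count.intake[T][:, 1].mean()),
        "pufa_share_longrun_pct": rel(policy.intake[T][:, 2].mean(), count.intake[T][:, 2].mean()),
        "chol_longrun_pct": rel(policy.chol_mean[T].mean(), count.chol_mean[T].mean()),
        "incident_cases_cum": cases_d,
        "premature_deaths_cum": deaths_d,
        "person_years_cum": py_delta,
        "workforce_person_years_cum": wf_delta,
        "person_years_per_100k": py_delta / py_count * 1e5,
        "workforce_per_100k": wf_delta / wf_count * 1e5,
        "ghg_longrun_mt": policy.ghg[T] - count.ghg[T],
    }
    rows = []
    for y in years:
        rows.append(
            {
                "year": y,
                "gdp_real_policy": policy.gdp_real(y),
                "gdp_real_count": count.gdp_real(y),
                "gdp_real_delta": policy.gdp_real(y) - count.gdp_real(y),
                "pop_delta": policy.pop[y].sum() - count.pop[y].sum(),
                "ls_delta": policy.ls[y].sum() - count.ls[y].sum(),
                "cases_delta": policy.levels[y][:, :, :, nf_ix].sum()
                - count.levels[y][:, :, :, nf_ix].sum(),
                "deaths_delta": policy.levels[y][:, :, :, fat_ix].sum()
                - count.levels[y][:, :, :, fat_ix].sum(),
                "ghg_delta": policy.ghg[y] - count.ghg[y],
            }
        )
    return ScenarioResult(
        spec=spec, summary=summary, per_year=pd.DataFrame(rows), policy=policy, count=count
    )


@dataclass
class CostEffectivenessReport:
    efficiency_loss_usd: float
    person_years: float
    cost_per_person_year: float
    cost_per_person_year_rounded: float
    ghg_mt: float
    carbon_price_usd_per_t: float
    ghg_value_usd: float
    ghg_adjusted_cost_rounded: float


def round_to(value: float, granularity: float) -> float:
    return float(np.round(value / granularity) * granularity)


def cost_effectiveness(
    efficiency_loss: float,
    person_years: float,
    ghg_mt: float = 0.0,
    carbon_price: float = 100.0,
    rounding: float = 10_000.0,
) -> CostEffectivenessReport:
    """Cost per person-year saved, with carbon-valuation adjustment.

    ``efficiency_loss`` is in USD, ``person_years`` > 0; ``ghg_mt`` is the
    avoided emission volume in Mt CO2-eq valued at ``carbon_price`` USD/t;
    ``rounding`` is the reporting granularity in USD.
    """
    if person_years <= 0:
        raise ScenarioError("person-years saved must be positive")
    cost = efficiency_loss / person_years
    ghg_value = ghg_mt * 1e6 * carbon_price
    adjusted = (efficiency_loss - ghg_value) / person_years
    return CostEffectivenessReport(
        efficiency_loss_usd=efficiency_loss,
        person_years=person_years,
        cost_per_person_year=cost,
        cost_per_person_year_rounded=round_to(cost, rounding) if efficiency_loss else 0.0,
        ghg_mt=ghg_mt,
        carbon_price_usd_per_t=carbon_price,
        ghg_value_usd=ghg_value,
        ghg_adjusted_cost_rounded=round_to(adjusted, rounding) if efficiency_loss else 0.0,
    )
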