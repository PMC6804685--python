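"""Recursive dynamics: factor updating and growth-trend calibration.

Capital accumulates from real investment with geometric depreciation; labour
supplies are fed in from the demographic/feedback chain; regional land
endowments are fixed.  Dynamic calibration finds the productivity-trend path
hitting a target real GDP growth rate year by year; the price-trend (CPI) path
is then set analytically — nominal variables are homogeneous of degree one in
the CPI target — so nominal GDP grows at its own target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .calibrate import CgeParams
from .model import Closure, Equilibrium, solve_period

#: Annual capital depreciation rate.
DEPRECIATION = 0.05


@dataclass
class EconomyState:
    """Exogenous per-year inputs to the within-period solve."""

    year: int
    fs: np.ndarray          # factor supplies (F,)
    capital: float
    capital0: float
    tfp: float = 1.0
    cpi: float = 1.0

    def copy(self) -> "EconomyState":
        return replace(self, fs=self.fs.copy())


def initial_state(params: CgeParams, year: int = 2015, growth_target: float = 0.039) -> EconomyState:
    """Base-year state; the capital stock is scaled so that base-year net
    capital growth equals the target growth rate (steady-growth calibration)."""
    k0 = float(params.qinv0.sum()) / (growth_target + DEPRECIATION)
    return EconomyState(year=year, fs=params.fs0.copy(), capital=k0, capital0=k0)


def advance(
    state: EconomyState,
    eq: Equilibrium,
    params: CgeParams,
    labour: dict[int, float] | None = None,
    depreciation: float = DEPRECIATION,
) -> EconomyState:
    """Advance the state one year after an equilibrium solve.

    Capital: K(t+1) = (1-d) K(t) + real investment.  ``labour`` maps factor
    indices to next-year supplies (from the demographic chain); land stays
    fixed; capital services scale with the stock.
    """
    new_capital = (1.0 - depreciation) * state.capital + float(eq.qinv.sum())
    if new_capital < 0:
        raise ValueError("negative capital stock")
    fs = state.fs.copy()
    fs[params.capital_factor] = params.fs0[params.capital_factor] * new_capital / state.capital0
    if labour:
        for f, supply in labour.items():
            fs[f] = supply
    return EconomyState(
        year=state.year + 1,
        fs=fs,
        capital=new_capital,
        capital0=state.capital0,
        tfp=state.tfp,
        cpi=state.cpi,
    )


@dataclass
class GrowthTrends:
    """Calibrated productivity and price-trend paths (by simulation year)."""

    tfp: dict[int, float] = field(default_factory=dict)
    cpi: dict[int, float] = field(default_factory=dict)
    real_target: float = 0.039
    nominal_target: float = 0.062


def run_forward(
    params: CgeParams,
    state0: EconomyState,
    years: list[int],
    trends: GrowthTrends,
    labour_path: dict[int, dict[int, float]] | None = None,
    tm: np.ndarray | None = None,
) -> list[Equilibrium]:
    """Solve a path of equilibria under given trend factors (no calibration)."""
    labour_path = labour_path or {}
    tm = params.tm0 if tm is None else tm
    base_eq = solve_period(params, state0, tm, Closure())
    state, eq = state0, base_eq
    path = []
    for year in years:
        state = advance(state, eq, params, labour=labour_path.get(year))
        state.year = year
        state.tfp = trends.tfp[year]
        state.cpi = trends.cpi[year]
        eq = solve_period(params, state, tm, Closure(), guess=eq.guess)
        path.append(eq)
    return path


def dynamic_calibrate(
    params: CgeParams,
    state0: EconomyState,
    years: list[int],
    labour_path: dict[int, dict[int, float]] | None = None,
    real_target: float = 0.039,
    nominal_target: float = 0.062,
    real_levels: dict[int, float] | None = None,
    rtol: float = 1e-9,
) -> tuple[GrowthTrends, list[Equilibrium]]:
    """Calibrate trend factors so the counterfactual hits both growth targets.

    For each year a scalar root-find on the productivity factor matches real
    GDP to its compound-growth target (or to an explicit per-year level from
    ``real_levels``); the CPI target is then rescaled exactly (homogeneity) so
    nominal GDP matches the nominal-growth path.  Returns the trends and the
    counterfactual equilibrium path.

    ``labour_path[year]`` maps labour-factor indices to that year's supplies.
    """
    trends = GrowthTrends(real_target=real_target, nominal_target=nominal_target)
    path: list[Equilibrium] = []
    labour_path = labour_path or {}

    base_eq = solve_period(params, state0, params.tm0, Closure())
    real_prev, nominal_prev = base_eq.gdp_real, base_eq.gdp_nominal
    state = state0
    guess = base_eq.guess
    tfp_guess = 1.0
    for year in years:
        state = advance(state, base_eq if not path else path[-1], params,
                        labour=labour_path.get(year))
        state.year = year
        real_target_level = (
            real_levels[year] if real_levels is not None else real_prev * (1.0 + real_target)
        )

        def gap(log_a, _state=state, _guess=guess):
            s = _state.copy()
            s.tfp = float(np.exp(log_a))
            eq = solve_period(params, s, params.tm0, Closure(), guess=_guess)
            return eq.gdp_real / real_target_level - 1.0, eq

        # secant iteration on log TFP
        a = np.log(tfp_guess)
        f_a, eq_a = gap(a)
        b = a + 0.01
        f_b, eq_b = gap(b)
        eq = eq_b
        for _ in range(60):
            if abs(f_b) < rtol:
                break
            if f_b == f_a:
                raise RuntimeError("productivity trend search stalled")
            a, b, f_a = b, b - f_b * (b - a) / (f_b - f_a), f_b
            f_b, eq = gap(b)
        else:
            raise RuntimeError(f"productivity trend search failed in {year}")
        state.tfp = float(np.exp(b))
        tfp_guess = state.tfp

        # exact nominal rescaling via CPI homogeneity
        nominal_target_level = nominal_prev * (1.0 + nominal_target)
        scale = nominal_target_level / eq.gdp_nominal
        state.cpi = state.cpi * scale
        eq = solve_period(params, state, params.tm0, Closure(), guess=eq.guess)
        if abs(eq.gdp_nominal / nominal_target_level - 1.0) > rtol * 10:
            raise RuntimeError(f"nominal calibration failed in {year}")

        trends.tfp[year] = state.tfp
        trends.cpi[year] = state.cpi
        path.append(eq)
        guess = eq.guess
        real_prev, nominal_prev = eq.gdp_real, eq.gdp_nominal
    return trends, path
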