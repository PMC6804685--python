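"""Within-period equilibrium: simultaneous market clearing under a closure.

The unknowns are domestic supply prices, factor wages, the exchange rate,
activity levels, the investment and government scale factors and the GDP
deflator (plus a savings-rate scaling in the efficiency closure), solved in
logs with a damped Newton method (``scipy.optimize.root``).  Prices clear all
commodity and factor markets, a flexible real exchange rate clears the fixed
current account, and the consumer price index is the numéraire.  One factor
market equation is dropped (Walras' law); its residual is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .calibrate import CgeParams


class SolverError(RuntimeError):
    """Equilibrium solver failed; carries the last residual vector."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class Closure:
    """Macro closure for one within-period solve.

    mode:
      ``ratio``      – real government consumption keeps its base share of real
                       absorption (counterfactual rule);
      ``fixed_gov``  – real government consumption pinned to ``gov_real_target``;
      ``efficiency`` – additionally pins aggregate real private consumption to
                       ``cons_real_target`` through a uniform household
                       savings-rate scaling.
    """

    mode: str = "ratio"
    gov_real_target: float | None = None
    cons_real_target: float | None = None
    #: policy-minus-counterfactual private health costs per household, real terms
    hcp_real: np.ndarray | None = None
    #: policy-minus-counterfactual public health costs, real terms
    hcg_real: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("ratio", "fixed_gov", "efficiency"):
            raise ValueError(f"unknown closure mode {self.mode!r}")
        if self.mode in ("fixed_gov", "efficiency") and self.gov_real_target is None:
            raise ValueError(f"closure {self.mode!r} needs gov_real_target")
        if self.mode == "efficiency" and self.cons_real_target is None:
            raise ValueError("efficiency closure needs cons_real_target")


@dataclass
class Equilibrium:
    """Solved within-period state: all prices, quantities and accounts."""

    year: int
    pd_: np.ndarray
    pq: np.ndarray
    pm: np.ndarray
    pe: np.ndarray
    pva: np.ndarray
    wf: np.ndarray
    exr: float
    gdpdef: float
    cpi: float
    qa: np.ndarray
    qva: np.ndarray
    d: np.ndarray
    e: np.ndarray
    m: np.ndarray
    qq: np.ndarray
    x: np.ndarray          # (C, H) household consumption quantities
    eh: np.ndarray
    qg: np.ndarray
    qinv: np.ndarray
    fdem: np.ndarray       # (F, A) factor allocations
    tariff_revenue: float
    gdp_nominal: float
    gdp_real: float
    cons_real: float
    gov_real: float
    invadj: float
    govadj: float
    savadj: float
    walras: float
    resid_max: float
    guess: np.ndarray = field(repr=False, default=None)

    def land_allocation(self, params: CgeParams) -> np.ndarray:
        """(ag activity, land factor) allocation matrix."""
        return self.fdem[np.ix_(params.land_factors, params.ag_activities)].T.copy()


def _unpack(params: CgeParams, closure: Closure, u: np.ndarray):
    n_c, n_f = params.n_c, params.n_f
    i = 0
    pd_ = np.exp(u[i : i + n_c]); i += n_c
    wf = np.exp(u[i : i + n_f]); i += n_f
    exr = float(np.exp(u[i])); i += 1
    qa = np.exp(u[i : i + n_c]); i += n_c
    invadj = float(np.exp(u[i])); i += 1
    govadj = float(np.exp(u[i])); i += 1
    gdpdef = float(np.exp(u[i])); i += 1
    savadj = 1.0
    if closure.mode == "efficiency":
        savadj = float(np.exp(u[i])); i += 1
    return pd_, wf, exr, qa, invadj, govadj, gdpdef, savadj


def _n_unknowns(params: CgeParams, closure: Closure) -> int:
    return 2 * params.n_c + params.n_f + 4 + (1 if closure.mode == "efficiency" else 0)


def _system(
    params: CgeParams,
    u: np.ndarray,
    tm: np.ndarray,
    fs: np.ndarray,
    tfp: float,
    cpibar: float,
    closure: Closure,
    year: int,
    full: bool,
):
    """Residual vector (and optionally the full equilibrium record)."""
    n_c, n_h = params.n_c, params.n_h
    u = np.clip(u, -30.0, 30.0)  # keep trial points finite in exp space
    pd_, wf, exr, qa, invadj, govadj, gdpdef, savadj = _unpack(params, closure, u)
    scale = params.gdp_real0

    pm = params.pwm * (1.0 + tm) * exr
    pe = params.pwe * exr

    pq = np.empty(n_c)
    px = np.empty(n_c)
    for c in range(n_c):
        pq[c] = params.armington[c].dual_price(np.array([pd_[c], pm[c]])) if params.armington[c] else pd_[c]
        px[c] = params.cet[c].dual_price(np.array([pd_[c], pe[c]])) if params.cet[c] else pd_[c]

    pinta = params.ica.T @ pq
    pva = np.empty(n_c)
    pa = np.empty(n_c)
    for a in range(n_c):
        pva[a] = params.va_nests[a].dual_price(wf[params.va_masks[a]], shift=tfp)
        if params.top_nests[a] is not None:
            pa[a] = params.top_nests[a].dual_price(np.array([pva[a], pinta[a]]))
        else:
            pa[a] = pva[a]

    # production quantities from the nests
    qva = np.empty(n_c)
    qinta = np.zeros(n_c)
    fdem = np.zeros((params.n_f, n_c))
    for a in range(n_c):
        if params.top_nests[a] is not None:
            qva[a], qinta[a] = params.top_nests[a].demands(qa[a], np.array([pva[a], pinta[a]]))
        else:
            qva[a] = qa[a]
        fdem[params.va_masks[a], a] = params.va_nests[a].demands(qva[a], wf[params.va_masks[a]], shift=tfp)
    qint = params.ica * qinta[None, :]

    # trade allocation of output
    d_s = np.empty(n_c)
    e_s = np.zeros(n_c)
    for c in range(n_c):
        if params.cet[c]:
            d_s[c], e_s[c] = params.cet[c].supplies(qa[c], np.array([pd_[c], pe[c]]))
        else:
            d_s[c] = qa[c]

    # institutions; the household capital pool is net of the government share
    # and the fixed foreign-currency repatriation
    cap = params.capital_factor
    yf = wf * fdem.sum(axis=1)
    hh_pool = yf.copy()
    hh_pool[cap] = yf[cap] * (1.0 - params.capgov_share) - params.caprow_fx * exr
    yh = params.shry @ hh_pool + params.tr0 * cpibar + params.rem0 * exr
    tax = params.tau * yh
    sav = params.mps * savadj * (yh - tax)
    hcp = (closure.hcp_real if closure.hcp_real is not None else np.zeros(n_h)) * gdpdef
    eh = yh - tax - sav - hcp
    x = np.empty((n_c, n_h))
    for h in range(n_h):
        x[:, h] = params.demand_systems[h](pq, float(eh[h]), gdpdef)
    srv = params.services_index
    qhp = float(hcp.sum()) / pq[srv]
    qhg = closure.hcg_real * gdpdef / pq[srv]

    qg = govadj * params.qg0
    qinv = invadj * params.qinv0

    # composite commodity demand and import allocation
    qq = qint.sum(axis=1) + x.sum(axis=1) + qg + qinv
    qq[srv] += qhp + qhg
    d_d = np.empty(n_c)
    m = np.zeros(n_c)
    for c in range(n_c):
        if params.armington[c]:
            d_d[c], m[c] = params.armington[c].demands(qq[c], np.array([pd_[c], pm[c]]))
        else:
            d_d[c] = qq[c]

    tariff_revenue = float((tm * params.pwm * m) @ np.ones(n_c) * exr)
    ygov = tariff_revenue + float(tax.sum()) + params.capgov_share * yf[cap]
    gov_spend = float(pq @ qg) + float(params.tr0.sum()) * cpibar + closure.hcg_real * gdpdef
    gov_sav = ygov - gov_spend

    cons_real = float(x.sum())
    gov_real = float(qg.sum())
    inv_real = float(qinv.sum())
    absorption = cons_real + gov_real + inv_real + qhp + qhg

    gdp_nominal = (
        float(pq @ (x.sum(axis=1) + qg + qinv))
        + pq[srv] * (qhp + qhg)
        + exr * float(params.pwe @ e_s - params.pwm @ m)
    )
    gdp_real = cons_real + qhp + qhg + gov_real + inv_real + float(e_s.sum() - m.sum())

    # Walras' law: with factor incomes paid on demanded quantities, one
    # commodity market equation is implied by the budget identities; drop the
    # last sector's and report its gap as the Walras residual.
    dropped = n_c - 1
    res = np.empty(_n_unknowns(params, closure))
    i = 0
    res[i : i + n_c] = np.log(pa / px); i += n_c                     # zero profit
    for c in range(n_c):                                             # commodity markets
        if c == dropped:
            continue
        res[i] = np.log(d_s[c] / d_d[c]); i += 1
    for f in range(params.n_f):                                      # factor markets
        res[i] = (fdem[f].sum() - fs[f]) / fs[f]; i += 1
    # current account (foreign currency); a fully closed economy pins the
    # exchange rate instead
    has_ext = (
        params.m0.sum() + params.e0.sum() + abs(params.caprow_fx)
        + params.rem0.sum() + abs(params.fsav0)
    ) > 0
    if has_ext:
        res[i] = (
            float(params.pwm @ m)
            + params.caprow_fx
            - float(params.pwe @ e_s)
            - float(params.rem0.sum())
            - params.fsav0
        ) / scale
    else:
        res[i] = np.log(exr)
    i += 1
    # savings-investment balance (degenerate without base investment)
    if params.qinv0.sum() > 0:
        res[i] = (float(pq @ qinv) - (float(sav.sum()) + gov_sav + params.fsav0 * exr)) / scale
    else:
        res[i] = np.log(invadj)
    i += 1
    # government closure (degenerate without base government demand)
    if params.qg0.sum() == 0:
        res[i] = np.log(govadj)
    elif closure.mode == "ratio":
        res[i] = gov_real / absorption - params.gov_ratio0
    else:
        res[i] = np.log(gov_real / closure.gov_real_target)
    i += 1
    # numéraire: CPI equals its exogenous trend value
    res[i] = np.log(float(params.cpi_weights @ pq) / cpibar); i += 1
    # GDP deflator definition
    res[i] = np.log(gdp_nominal / (gdp_real * gdpdef)); i += 1
    if closure.mode == "efficiency":
        res[i] = np.log(cons_real / closure.cons_real_target); i += 1

    if not full:
        return res

    walras = float(np.log(d_s[dropped] / d_d[dropped]))
    eq = Equilibrium(
        year=year,
        pd_=pd_, pq=pq, pm=pm, pe=pe, pva=pva, wf=wf, exr=exr,
        gdpdef=gdpdef, cpi=cpibar,
        qa=qa, qva=qva, d=d_s, e=e_s, m=m, qq=qq, x=x, eh=eh,
        qg=qg, qinv=qinv, fdem=fdem,
        tariff_revenue=tariff_revenue,
        gdp_nominal=gdp_nominal, gdp_real=gdp_real,
        cons_real=cons_real, gov_real=gov_real,
        invadj=invadj, govadj=govadj, savadj=savadj,
        walras=walras,
        resid_max=float(np.max(np.abs(res))),
        guess=u.copy(),
    )
    return res, eq


def solve_period(
    params: CgeParams,
    state,
    tm: np.ndarray,
    closure: Closure | None = None,
    guess: np.ndarray | None = None,
    tol: float = 1e-11,
) -> Equilibrium:
    """Solve one year's equilibrium.

    ``state`` provides factor supplies, the productivity factor and the CPI
    target (see :class:`fiscalfood.cge.dynamics.EconomyState`).  A previous
    solution's ``guess`` vector warm-starts the Newton iteration.  On failure,
    a homotopy path in the tariff vector is attempted before giving up.
    """
    closure = closure or Closure()
    tm = np.asarray(tm, dtype=float)
    if np.any(tm < 0):
        raise ValueError("tariff rates must be non-negative")
    fs, tfp, cpibar, year = state.fs, state.tfp, state.cpi, state.year

    n = _n_unknowns(params, closure)
    if guess is None or guess.size != n:
        guess = np.zeros(n)
        # seed nominal unknowns at the CPI trend level
        n_c, n_f = params.n_c, params.n_f
        guess[: n_c + n_f + 1] = np.log(cpibar)
        guess[n_c + n_f + 1 : 2 * n_c + n_f + 1] = np.log(params.qa0)
        guess[2 * n_c + n_f + 3] = np.log(cpibar)  # deflator

    def make_fun(tm_eval):
        def fun(u):
            with np.errstate(all="ignore"):
                r = _system(params, u, tm_eval, fs, tfp, cpibar, closure, year, full=False)
            return np.where(np.isfinite(r), r, 1e6)
        return fun

    fun = make_fun(tm)
    u, ok = _damped_newton(fun, guess, tol)
    if not ok:
        # homotopy in the tariff vector from the calibrated base
        u = guess.copy()
        for step in np.linspace(0.2, 1.0, 5):
            u, ok = _damped_newton(make_fun(params.tm0 + step * (tm - params.tm0)), u, tol)
        if not ok:
            sol = optimize.root(fun, guess, method="hybr", options={"xtol": 1e-13, "maxfev": 20000})
            u, ok = sol.x, np.max(np.abs(fun(sol.x))) <= tol * 100
    res = fun(u)
    if np.max(np.abs(res)) > tol * 100:
        raise SolverError(
            f"equilibrium solver failed in year {year}: max residual {np.max(np.abs(res)):.3g}",
            residuals=res,
        )
    _, eq = _system(params, u, tm, fs, tfp, cpibar, closure, year, full=True)
    return eq


def _damped_newton(
    fun, u0: np.ndarray, tol: float, max_iter: int = 80, fd_step: float = 1e-7
) -> tuple[np.ndarray, bool]:
    """Newton iteration with forward-difference Jacobian and backtracking."""
    u = u0.copy()
    r = fun(u)
    for _ in range(max_iter):
        norm = float(np.max(np.abs(r)))
        if norm <= tol:
            return u, True
        jac = np.empty((r.size, u.size))
        for j in range(u.size):
            up = u.copy()
            up[j] += fd_step
            jac[:, j] = (fun(up) - r) / fd_step
        try:
            du = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            du = np.linalg.lstsq(jac, -r, rcond=None)[0]
        step = 1.0
        improved = False
        for _ in range(50):
            rn = fun(u + step * du)
            if np.max(np.abs(rn)) < norm * (1.0 - 1e-4 * step):
                u, r = u + step * du, rn
                improved = True
                break
            step *= 0.5
        if not improved:
            return u, False
    return u, float(np.max(np.abs(r))) <= tol
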