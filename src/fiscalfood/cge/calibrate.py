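"""Benchmark calibration of the static general-equilibrium core from a SAM.

The model follows the standard single-country structure: nested CES production
(top nest: value added vs aggregate intermediates; bottom nest: factors),
Leontief intermediate composition, CES import aggregation and CET export
transformation per commodity, households with calibrated AIDS expenditure
systems, a government collecting tariffs and direct taxes, savings-driven
investment and a fixed-foreign-savings external account.

All base prices are normalized to one (import composite prices embed the base
tariff), so base quantities equal SAM values and benchmark replication is exact
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ces import CesNest, CetNest
from ..demand import DemandSystem, calibrate_aids
from ..sam import AccountKind, SocialAccountingMatrix

#: Default substitution/transformation elasticities.
DEFAULT_ELASTICITIES = {
    "production_top": 0.8,
    "production_factors": 0.6,
    "armington": 0.8,
    "cet": 1.6,
}


class CalibrationError(ValueError):
    pass


@dataclass
class CgeParams:
    """Calibrated model parameters and benchmark flows (base prices = 1)."""

    sectors: list[str]
    factors: list[str]
    households: list[str]

    # production
    top_nests: list[CesNest]          # per activity: (QVA, QINTA)
    va_nests: list[CesNest]           # per activity, over factor subset
    va_masks: list[np.ndarray]        # factor index arrays per activity
    ica: np.ndarray                   # (C, A) intermediate coefficients

    # trade
    armington: list[CetNest | CesNest | None]
    cet: list[CetNest | None]
    tm0: np.ndarray
    pwm: np.ndarray
    pwe: np.ndarray

    # institutions
    demand_systems: list[DemandSystem]
    shry: np.ndarray                  # (H, F) household shares of factor income
    capgov_share: float
    #: capital repatriation abroad, fixed in foreign currency (keeps the real
    #: trade balance pinned by the current-account closure)
    caprow_fx: float
    tau: np.ndarray                   # direct tax rates per household
    mps: np.ndarray                   # marginal propensities to save
    tr0: np.ndarray                   # government transfers per household
    rem0: np.ndarray                  # foreign remittances per household
    fsav0: float

    # final demand patterns
    qg0: np.ndarray
    qinv0: np.ndarray
    cpi_weights: np.ndarray
    gov_ratio0: float                 # real gov consumption / real absorption
    services_index: int

    # benchmark quantities
    qa0: np.ndarray
    qva0: np.ndarray
    qinta0: np.ndarray
    va0: np.ndarray                   # (F, A)
    d0: np.ndarray
    e0: np.ndarray
    m0: np.ndarray
    x0: np.ndarray                    # (C, H)
    eh0: np.ndarray
    fs0: np.ndarray                   # base factor supplies
    gdp_real0: float

    # structural index sets
    ag_activities: list[int] = field(default_factory=list)
    land_factors: list[int] = field(default_factory=list)
    labour_factors: list[int] = field(default_factory=list)
    capital_factor: int = -1

    @property
    def n_c(self) -> int:
        return len(self.sectors)

    @property
    def n_f(self) -> int:
        return len(self.factors)

    @property
    def n_h(self) -> int:
        return len(self.households)


def calibrate(
    sam: SocialAccountingMatrix,
    demand_inputs=None,
    elasticities: dict | None = None,
) -> CgeParams:
    """Calibrate the model to a balanced SAM.

    ``demand_inputs`` supplies per-household income/price elasticities (a
    :class:`fiscalfood.fixtures.DemandInputs`); base shares always come from
    the SAM itself so benchmark replication is exact.  Homothetic unitary
    systems are used when no elasticities are given.
    """
    sam.require_balanced()
    elas = dict(DEFAULT_ELASTICITIES, **(elasticities or {}))
    frame = sam.to_frame()

    acts = sam.of_kind(AccountKind.ACTIVITY)
    coms = sam.of_kind(AccountKind.COMMODITY)
    facs = sam.of_kind(AccountKind.FACTOR)
    hhs = sam.of_kind(AccountKind.HOUSEHOLD)
    sectors = [a.split(".", 1)[1] for a in acts]
    if [c.split(".", 1)[1] for c in coms] != sectors:
        raise CalibrationError("activities and commodities must be one-to-one")
    factors = [f.split(".", 1)[1] for f in facs]
    households = [h.split(".", 1)[1] for h in hhs]
    n_c, n_f, n_h = len(sectors), len(factors), len(households)

    e0 = frame.loc[coms, "row"].to_numpy()
    m0 = frame.loc["row", coms].to_numpy()
    tar0 = frame.loc["gov", coms].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tm0 = np.where(m0 > 0, tar0 / np.where(m0 > 0, m0, 1.0), 0.0)
    sales0 = frame.loc[coms].sum(axis=1).to_numpy() - e0
    d0 = sales0 - m0 * (1.0 + tm0)
    if np.any(d0 <= 0):
        raise CalibrationError("non-positive domestic supply implied by the SAM")
    qx0 = d0 + e0

    qint0 = frame.loc[coms, acts].to_numpy()
    va0 = frame.loc[facs, acts].to_numpy()
    qinta0 = qint0.sum(axis=0)
    qva0 = va0.sum(axis=0)
    qa0 = qva0 + qinta0
    if np.max(np.abs(qa0 - qx0)) > 1e-6 * max(qx0.max(), 1.0):
        raise CalibrationError("activity costs do not exhaust output value (zero profit)")
    if np.any(qva0 <= 0):
        raise CalibrationError("zero value added where share parameters are required")
    with np.errstate(divide="ignore", invalid="ignore"):
        ica = np.where(qinta0 > 0, qint0 / np.where(qinta0 > 0, qinta0, 1.0), 0.0)

    top_nests, va_nests, va_masks = [], [], []
    for a in range(n_c):
        # activities without intermediates collapse to a pure value-added nest
        top_nests.append(
            CesNest.calibrate(
                np.array([qva0[a], qinta0[a]]), np.ones(2), elas["production_top"]
            )
            if qinta0[a] > 0
            else None
        )
        mask = np.flatnonzero(va0[:, a] > 0)
        if mask.size == 0:
            raise CalibrationError(f"activity {sectors[a]} uses no factors")
        va_masks.append(mask)
        va_nests.append(
            CesNest.calibrate(va0[mask, a], np.ones(mask.size), elas["production_factors"])
        )

    armington: list = []
    cet: list = []
    for c in range(n_c):
        if m0[c] > 0:
            armington.append(
                CesNest.calibrate(
                    np.array([d0[c], m0[c]]),
                    np.array([1.0, 1.0 + tm0[c]]),
                    elas["armington"],
                )
            )
        else:
            armington.append(None)
        if e0[c] > 0:
            cet.append(CetNest.calibrate(np.array([d0[c], e0[c]]), np.ones(2), elas["cet"]))
        else:
            cet.append(None)

    x0 = frame.loc[coms, hhs].to_numpy()
    eh0 = x0.sum(axis=0)
    yf0 = va0.sum(axis=1)
    fac2hh = frame.loc[hhs, facs].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        shry = np.where(yf0 > 0, fac2hh / np.where(yf0 > 0, yf0, 1.0), 0.0)
    cap_ix = factors.index("capital") if "capital" in factors else n_f - 1
    cap_lab = facs[cap_ix]
    capgov_share = float(frame.loc["gov", cap_lab] / yf0[cap_ix]) if yf0[cap_ix] > 0 else 0.0
    caprow_fx = float(frame.loc["row", cap_lab])
    # households own capital income net of the government share and the fixed
    # repatriation; normalize their base capital weights accordingly
    hh_cap_base = yf0[cap_ix] - capgov_share * yf0[cap_ix] - caprow_fx
    if hh_cap_base > 0:
        shry[:, cap_ix] = shry[:, cap_ix] * yf0[cap_ix] / hh_cap_base

    tr0 = frame.loc[hhs, "gov"].to_numpy()
    rem0 = frame.loc[hhs, "row"].to_numpy()
    yh0 = fac2hh.sum(axis=1) + tr0 + rem0
    tax0 = frame.loc["gov", hhs].to_numpy()
    sav0 = frame.loc["s-i", hhs].to_numpy()
    tau = tax0 / yh0
    mps = sav0 / (yh0 - tax0)
    if np.max(np.abs((1 - tau) * (1 - mps) * yh0 - eh0)) > 1e-6 * eh0.max():
        raise CalibrationError("household budget does not close at the benchmark")

    qg0 = frame.loc[coms, "gov"].to_numpy()
    qinv0 = frame.loc[coms, "s-i"].to_numpy()
    fsav0 = float(frame.loc["s-i", "row"] - frame.loc["row", "s-i"])

    demand_systems = []
    for h in range(n_h):
        w0 = x0[:, h] / eh0[h]
        if demand_inputs is not None:
            eta = demand_inputs.income_elasticities[h]
            eps = demand_inputs.price_elasticities[h]
        else:
            eta = np.ones(n_c)
            eps = -np.eye(n_c)
        demand_systems.append(
            calibrate_aids(
                w0, eta, eps, commodities=sectors, base_expenditure=float(eh0[h])
            )
        )

    cons0 = x0.sum(axis=1)
    cpi_weights = cons0 / cons0.sum()
    c_real0 = float(cons0.sum())
    g_real0 = float(qg0.sum())
    i_real0 = float(qinv0.sum())
    gov_ratio0 = g_real0 / (c_real0 + g_real0 + i_real0)
    gdp_real0 = c_real0 + g_real0 + i_real0 + float(e0.sum()) - float(m0.sum())
    if abs(gdp_real0 - (qva0.sum() + tar0.sum())) > 1e-6 * gdp_real0:
        raise CalibrationError("GDP identity violated at the benchmark")

    services_index = sectors.index("services") if "services" in sectors else n_c - 1
    land_factors = [i for i, f in enumerate(factors) if f.startswith("land_")]
    ag_activities = sorted({a for a in range(n_c) for f in land_factors if va0[f, a] > 0})
    labour_factors = [i for i, f in enumerate(factors) if f.startswith("labour_")]

    return CgeParams(
        sectors=sectors,
        factors=factors,
        households=households,
        top_nests=top_nests,
        va_nests=va_nests,
        va_masks=va_masks,
        ica=ica,
        armington=armington,
        cet=cet,
        tm0=tm0,
        pwm=np.ones(n_c),
        pwe=np.ones(n_c),
        demand_systems=demand_systems,
        shry=shry,
        capgov_share=capgov_share,
        caprow_fx=caprow_fx,
        tau=tau,
        mps=mps,
        tr0=tr0,
        rem0=rem0,
        fsav0=fsav0,
        qg0=qg0,
        qinv0=qinv0,
        cpi_weights=cpi_weights,
        gov_ratio0=gov_ratio0,
        services_index=services_index,
        qa0=qa0,
        qva0=qva0,
        qinta0=qinta0,
        va0=va0,
        d0=d0,
        e0=e0,
        m0=m0,
        x0=x0,
        eh0=eh0,
        fs0=yf0,
        gdp_real0=gdp_real0,
        ag_activities=ag_activities,
        land_factors=land_factors,
        labour_factors=labour_factors,
        capital_factor=cap_ix,
    )


def recovered_tariff_rates(params: CgeParams) -> np.ndarray:
    """Tariff rates implied by the calibration (revenue / cif import value)."""
    return params.tm0.copy()


def average_tariff(params: CgeParams) -> float:
    """Import-value-weighted average tariff rate."""
    return float((params.tm0 @ params.m0) / params.m0.sum())
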