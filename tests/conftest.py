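import logging

import numpy as np
import pytest
from scipy.optimize import brentq

from fiscalfood import make_fixtures, aggregate
from fiscalfood.cge import calibrate, initial_state, solve_period
from fiscalfood.sam import SocialAccountingMatrix
from fiscalfood.scenarios import SimulationEngine

logging.getLogger("fiscalfood").setLevel(logging.ERROR)


def build_cd_toy():
    """Closed 2-activity, 2-factor Cobb-Douglas economy with a closed form.

    Consumer shares theta, labour cost shares alpha_L per sector, saving rate
    s, investment spent on good y.  Returns (params, primitives).
    """
    theta = np.array([0.45, 0.55])
    alpha_l = np.array([0.7, 0.4])
    s = 0.1
    y0 = 150.0
    cons = theta * (1 - s) * y0
    inv = np.array([0.0, s * y0])
    dem = cons + inv  # sector demand values
    lab = alpha_l * dem
    cap = (1 - alpha_l) * dem
    labels = ["act.x", "act.y", "com.x", "com.y", "fac.labour", "fac.capital",
              "hh.h", "gov", "s-i", "row"]
    ix = {lab_: i for i, lab_ in enumerate(labels)}
    m = np.zeros((10, 10))
    for j, sec in enumerate(["x", "y"]):
        m[ix[f"act.{sec}"], ix[f"com.{sec}"]] = dem[j]
        m[ix["fac.labour"], ix[f"act.{sec}"]] = lab[j]
        m[ix["fac.capital"], ix[f"act.{sec}"]] = cap[j]
        m[ix[f"com.{sec}"], ix["hh.h"]] = cons[j]
        m[ix[f"com.{sec}"], ix["s-i"]] = inv[j]
    m[ix["hh.h"], ix["fac.labour"]] = lab.sum()
    m[ix["hh.h"], ix["fac.capital"]] = cap.sum()
    m[ix["s-i"], ix["hh.h"]] = s * y0
    sam = SocialAccountingMatrix(labels, m)
    params = calibrate(sam, elasticities={"production_factors": 1.0})
    prim = {
        "theta": theta, "alpha_l": alpha_l, "s": s,
        "labour0": lab.sum(), "capital0": cap.sum(),
    }
    return params, prim


def cd_toy_closed_form(prim, labour, capital):
    """Analytic equilibrium of the Cobb-Douglas toy at given factor supplies."""
    theta, alpha_l, s = prim["theta"], prim["alpha_l"], prim["s"]
    phi = theta * (1 - s) + np.array([0.0, s])  # demand-value shares of income
    lab_share = float(alpha_l @ phi)            # labour share of total income
    cap_share = 1.0 - lab_share

    def cpi_gap(y):
        w = lab_share * y / labour
        r = cap_share * y / capital
        p = w**alpha_l * r ** (1 - alpha_l)
        return float(theta @ p) - 1.0

    y = brentq(cpi_gap, 1.0, 1e4, xtol=1e-13, rtol=1e-15)
    w = lab_share * y / labour
    r = cap_share * y / capital
    p = w**alpha_l * r ** (1 - alpha_l)
    q = phi * y / p
    return {"income": y, "w": w, "r": r, "prices": p, "quantities": q}


@pytest.fixture(scope="session")
def cd_toy():
    return build_cd_toy()


@pytest.fixture(scope="session")
def bundle():
    return make_fixtures()


@pytest.fixture(scope="session")
def coarse_sam(bundle):
    return aggregate(bundle.sam, bundle.smap)


@pytest.fixture(scope="session")
def params(coarse_sam, bundle):
    return calibrate(coarse_sam, bundle.demand)


@pytest.fixture(scope="session")
def base_state(params):
    return initial_state(params)


@pytest.fixture(scope="session")
def base_eq(params, base_state):
    return solve_period(params, base_state, params.tm0)


@pytest.fixture(scope="session")
def engine(bundle):
    return SimulationEngine(bundle)


@pytest.fixture(scope="session")
def trends(engine):
    return engine.trends()
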