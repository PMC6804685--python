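"""Deterministic synthetic fixture generator for the whole model pipeline.

`make_fixtures` builds, from a single seeded generator, a balanced 49-sector
social accounting matrix whose 8-sector aggregation reproduces the targeted
structural shares (import share of domestic sales, export share of production,
tariff rates, sales shares, household consumption shares), together with
demand-system elasticities, nutrient tables, biomarker distributions, clinical
lookup parameters, demographic baselines and vital rates, health-economic
parameters and land-use-change emission coefficients.

Regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import clinical, demography, feedbacks, luc, nutrition
from .sam import SectorMap, SocialAccountingMatrix, ras

DEFAULT_SEED = 20160101

COARSE_SECTORS = [
    "primary_food",
    "other_primary",
    "palm_oil",
    "other_oils",
    "processed_foods",
    "beverages",
    "manufacturing",
    "services",
]
FOOD_SECTORS = frozenset(
    ["primary_food", "palm_oil", "other_oils", "processed_foods", "beverages"]
)
AGRICULTURAL_SECTORS = ["primary_food", "other_primary"]

FINE_SECTORS: dict[str, list[str]] = {
    "primary_food": ["rice", "maize", "cassava", "sugarcane", "fruits_vegetables", "pulses_oilseeds"],
    "other_primary": ["rubber", "forestry", "fisheries", "livestock", "mining"],
    "palm_oil": ["palm_cooking_oil"],
    "other_oils": ["soybean_oil", "coconut_oil"],
    "processed_foods": [
        "milled_grains", "processed_meat", "processed_fish", "dairy", "refined_sugar",
        "bakery_confectionery", "canned_fruit_veg", "animal_feed", "sauces_condiments",
        "snack_foods",
    ],
    "beverages": ["alcoholic_beverages", "soft_drinks"],
    "manufacturing": [
        "textiles", "garments", "leather", "wood_products", "paper", "chemicals",
        "plastics", "petroleum_refining", "cement_ceramics", "basic_metals",
        "metal_products", "machinery", "electronics", "vehicles", "other_manufacturing",
    ],
    "services": [
        "construction", "utilities", "trade", "transport", "finance", "public_admin",
        "health_education", "other_services",
    ],
}

HOUSEHOLDS = [
    "bangkok",
    "central_rural", "central_urban",
    "north_rural", "north_urban",
    "northeast_rural", "northeast_urban",
    "south_rural", "south_urban",
]
FACTORS = [
    "land_central_east", "land_north", "land_northeast", "land_south",
    "labour_unskilled", "labour_skilled", "capital",
]
LAND_FACTORS = FACTORS[:4]


class FixtureError(ValueError):
    pass


def sector_map() -> SectorMap:
    mapping = {fine: coarse for coarse, fines in FINE_SECTORS.items() for fine in fines}
    fine = tuple(f for coarse in COARSE_SECTORS for f in FINE_SECTORS[coarse])
    return SectorMap(fine=fine, coarse=tuple(COARSE_SECTORS), mapping=mapping, food=FOOD_SECTORS)


# ---------------------------------------------------------------------------
# Structural share targets
# ---------------------------------------------------------------------------


@dataclass
class Table1Shares:
    """Per-coarse-sector structural targets (fractions, not percent).

    import_share    : imports / domestic sales value
    export_share    : exports / production value
    tariff_rate     : tariff revenue / cif import value
    sales_share     : sector share of total domestic sales (sums to 1)
    household_share : sector share of household consumption (sums to 1)
    """

    sectors: list[str]
    import_share: np.ndarray
    export_share: np.ndarray
    tariff_rate: np.ndarray
    sales_share: np.ndarray
    household_share: np.ndarray

    def __post_init__(self) -> None:
        for name in ("import_share", "export_share", "tariff_rate", "sales_share", "household_share"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.size != len(self.sectors):
                raise FixtureError(f"{name} does not cover all sectors")
            if np.any(arr < 0):
                raise FixtureError(f"{name} contains negative values")
        for name in ("sales_share", "household_share"):
            total = getattr(self, name).sum()
            if abs(total - 1.0) > 0.005:
                raise FixtureError(f"{name} sums to {total:.4f}, not 100%")
            setattr(self, name, getattr(self, name) / total)
        if np.any(self.import_share >= 1) or np.any(self.export_share >= 1):
            raise FixtureError("import/export shares must be below 100%")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sector": self.sectors,
                "import_share": self.import_share,
                "export_share": self.export_share,
                "tariff_rate": self.tariff_rate,
                "sales_share": self.sales_share,
                "household_share": self.household_share,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Table1Shares":
        return cls(
            sectors=list(frame["sector"]),
            import_share=frame["import_share"].to_numpy(),
            export_share=frame["export_share"].to_numpy(),
            tariff_rate=frame["tariff_rate"].to_numpy(),
            sales_share=frame["sales_share"].to_numpy(),
            household_share=frame["household_share"].to_numpy(),
        )


#: Target for the economy-wide import-weighted average tariff rate.
AVERAGE_TARIFF_TARGET = 0.016


def default_targets() -> Table1Shares:
    """Default structural targets for the eight aggregate sectors.

    The manufacturing tariff rate is solved so that the import-weighted
    average tariff across all sectors equals ``AVERAGE_TARIFF_TARGET``
    exactly (the per-sector published rates are rounded to one decimal and
    are mutually inconsistent with the published average otherwise).
    """
    import_share = np.array([5.3, 4.5, 3.1, 28.9, 10.4, 14.5, 39.1, 11.2]) / 100
    export_share = np.array([3.4, 6.1, 11.8, 20.9, 43.1, 9.8, 67.9, 13.8]) / 100
    sales_share = np.array([3.5, 2.2, 0.2, 0.1, 5.9, 1.8, 47.1, 39.3]) / 100
    household_share = np.array([4.9, 1.2, 0.4, 0.1, 8.0, 5.8, 28.1, 51.6]) / 100
    tariff = np.array([1.4, 0.3, 0.0, 0.2, 2.8, 22.7, np.nan, 0.0]) / 100
    imports = import_share * sales_share  # proportional import weights
    known = ~np.isnan(tariff)
    mfg = COARSE_SECTORS.index("manufacturing")
    tariff[mfg] = (
        AVERAGE_TARIFF_TARGET * imports.sum() - float(tariff[known] @ imports[known])
    ) / imports[mfg]
    return Table1Shares(
        sectors=list(COARSE_SECTORS),
        import_share=import_share,
        export_share=export_share,
        tariff_rate=tariff,
        sales_share=sales_share,
        household_share=household_share,
    )


def table1_shares(sam: SocialAccountingMatrix) -> pd.DataFrame:
    """Compute the five structural share columns from a coarse SAM."""
    frame = sam.to_frame()
    coms = [f"com.{s}" for s in COARSE_SECTORS]
    acts = [f"act.{s}" for s in COARSE_SECTORS]
    hhs = sam.of_kind(type(sam.kinds[0]).HOUSEHOLD)
    imports = frame.loc["row", coms].to_numpy()
    tariffs = frame.loc["gov", coms].to_numpy()
    exports = frame.loc[coms, "row"].to_numpy()
    # commodity receipts = domestic sales + export receipts passed to activities
    sales = frame.loc[coms].sum(axis=1).to_numpy() - exports
    production = frame.loc[acts].sum(axis=1).to_numpy()
    hh_cons = frame.loc[coms, hhs].sum(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        tariff_rate = np.where(imports > 0, tariffs / np.where(imports > 0, imports, 1.0), 0.0)
    return pd.DataFrame(
        {
            "sector": COARSE_SECTORS,
            "import_share": imports / sales,
            "export_share": exports / production,
            "tariff_rate": tariff_rate,
            "sales_share": sales / sales.sum(),
            "household_share": hh_cons / hh_cons.sum(),
            "average_tariff": tariffs.sum() / imports.sum(),
        }
    )


# ---------------------------------------------------------------------------
# SAM construction
# ---------------------------------------------------------------------------

_SCALE = 10_000.0           # total domestic sales value, model currency units
_CONSUMPTION_FRAC = 0.28    # household consumption / total sales
_GOV_TOTAL = 800.0
_INV_TOTAL = 2_200.0
_GOV_ALLOC = {"services": 0.85, "manufacturing": 0.10, "processed_foods": 0.05}
_INV_ALLOC = {"manufacturing": 0.60, "services": 0.40}
_INCOME_TAX = 0.05
_GOV_SAVING_TARGET = 0.02 * _SCALE
# intermediate-input intensity of gross output, before global rescaling
_INT_INTENSITY = {
    "primary_food": 0.45, "other_primary": 0.40, "palm_oil": 0.60, "other_oils": 0.65,
    "processed_foods": 0.62, "beverages": 0.55, "manufacturing": 0.65, "services": 0.35,
}
# factor shares of value added: (land, unskilled, skilled, capital)
_FACTOR_SHARES = {
    "primary_food": (0.40, 0.38, 0.07, 0.15),
    "other_primary": (0.35, 0.33, 0.08, 0.24),
    "palm_oil": (0.0, 0.40, 0.15, 0.45),
    "other_oils": (0.0, 0.38, 0.15, 0.47),
    "processed_foods": (0.0, 0.38, 0.15, 0.47),
    "beverages": (0.0, 0.35, 0.17, 0.48),
    "manufacturing": (0.0, 0.32, 0.16, 0.52),
    "services": (0.0, 0.35, 0.28, 0.37),
}
# capital income distribution beyond the household top-up
_CAP_TO_HH = 0.55
_INCOME_TAX_RATE = 0.10
_LAND_REGION_WEIGHTS = {
    "primary_food": (0.30, 0.22, 0.33, 0.15),
    "other_primary": (0.24, 0.20, 0.26, 0.30),
}
_HH_SPEND_WEIGHTS = np.array([0.28, 0.10, 0.09, 0.08, 0.07, 0.10, 0.08, 0.10, 0.10])
_HH_POP_WEIGHTS = np.array([0.15, 0.12, 0.08, 0.10, 0.06, 0.18, 0.07, 0.09, 0.05])
# affinity of each household to each land region (rows: households)
_HH_REGION = {
    "bangkok": "central_east",
    "central_rural": "central_east", "central_urban": "central_east",
    "north_rural": "north", "north_urban": "north",
    "northeast_rural": "northeast", "northeast_urban": "northeast",
    "south_rural": "south", "south_urban": "south",
}


def _build_coarse_sam(rng: np.random.Generator, targets: Table1Shares) -> SocialAccountingMatrix:
    sec = targets.sectors
    if sec != COARSE_SECTORS:
        raise FixtureError("targets must cover the eight coarse sectors in order")
    n = len(sec)
    sales = targets.sales_share * _SCALE
    imports = targets.import_share * sales
    tariffs = targets.tariff_rate * imports
    domestic = sales - imports * (1.0 + targets.tariff_rate)
    if np.any(domestic <= 0):
        raise FixtureError("import shares leave no domestic supply")
    production = domestic / (1.0 - targets.export_share)
    exports = targets.export_share * production

    cons_total = _CONSUMPTION_FRAC * _SCALE
    consumption = targets.household_share * cons_total
    gov = np.array([_GOV_ALLOC.get(s, 0.0) for s in sec]) * _GOV_TOTAL
    inv = np.array([_INV_ALLOC.get(s, 0.0) for s in sec]) * _INV_TOTAL
    intermediates = sales - consumption - gov - inv
    if np.any(intermediates < 0.01 * sales):
        bad = [s for s, v, m in zip(sec, intermediates, sales) if v < 0.01 * m]
        raise FixtureError(f"final demand exhausts sales for sectors {bad}: infeasible targets")

    # activity cost structure: rescale intermediate intensities so column
    # totals match the intermediate demand row totals
    theta = np.array([_INT_INTENSITY[s] for s in sec])
    k = intermediates.sum() / float(theta @ production)
    theta = theta * k
    if np.any(theta >= 0.9):
        raise FixtureError("intermediate intensity rescaling exceeded 0.9")
    col_int = theta * production
    value_added = production - col_int

    seed_int = np.outer(intermediates, col_int) / col_int.sum()
    seed_int *= rng.uniform(0.6, 1.4, size=seed_int.shape)
    qint, _ = ras(seed_int, intermediates, col_int, tol=1e-12)

    # factor payments
    fac = np.zeros((len(FACTORS), n))
    for j, s in enumerate(sec):
        land, unsk, sk, cap = _FACTOR_SHARES[s]
        if land > 0:
            w = np.array(_LAND_REGION_WEIGHTS[s])
            w = w * rng.uniform(0.9, 1.1, size=4)
            fac[:4, j] = land * value_added[j] * w / w.sum()
        fac[4, j] = unsk * value_added[j]
        fac[5, j] = sk * value_added[j]
        fac[6, j] = cap * value_added[j]
        fac[:, j] *= value_added[j] / fac[:, j].sum()

    # household consumption matrix (commodity x household) via RAS
    hw = _HH_SPEND_WEIGHTS / _HH_SPEND_WEIGHTS.sum()
    spend = hw * cons_total
    seed_x = np.outer(consumption, spend) / cons_total
    seed_x *= rng.uniform(0.7, 1.3, size=seed_x.shape)
    xch, _ = ras(seed_x, consumption, spend, tol=1e-12)

    # factor income to households: all land and labour plus a capital share;
    # the rest of capital income accrues to government and foreign owners
    yf = fac.sum(axis=1)
    cap_to_hh_total = _CAP_TO_HH * yf[6]

    fac2hh = np.zeros((len(HOUSEHOLDS), len(FACTORS)))
    for fi, fname in enumerate(FACTORS):
        if fname in LAND_FACTORS:
            region = fname.removeprefix("land_")
            weights = np.array(
                [1.0 if _HH_REGION[h] == region and h.endswith("_rural") else
                 (0.6 if _HH_REGION[h] == region else 0.02)
                 for h in HOUSEHOLDS]
            )
        elif fname == "labour_unskilled":
            weights = _HH_POP_WEIGHTS * np.array(
                [0.7 if (h == "bangkok" or h.endswith("_urban")) else 1.3 for h in HOUSEHOLDS]
            )
        elif fname == "labour_skilled":
            weights = _HH_SPEND_WEIGHTS * np.array(
                [1.4 if (h == "bangkok" or h.endswith("_urban")) else 0.6 for h in HOUSEHOLDS]
            )
        else:  # capital
            weights = _HH_SPEND_WEIGHTS.copy()
        weights = weights * rng.uniform(0.9, 1.1, size=len(HOUSEHOLDS))
        total = yf[fi] if fname != "capital" else cap_to_hh_total
        fac2hh[:, fi] = total * weights / weights.sum()

    fac_income_h = fac2hh.sum(axis=1)
    # transfers/remittances top up households whose implied saving would be
    # too low; otherwise saving is the budget residual
    transfers = np.zeros(len(HOUSEHOLDS))
    remittances = np.zeros(len(HOUSEHOLDS))
    for h in range(len(HOUSEHOLDS)):
        needed = spend[h] / ((1 - _INCOME_TAX_RATE) * (1 - 0.10))
        gap = needed - fac_income_h[h]
        if gap > 0:
            transfers[h] = 0.7 * gap
            remittances[h] = 0.3 * gap
    income_h = fac_income_h + transfers + remittances
    income_tax = _INCOME_TAX_RATE * income_h
    hh_saving = income_h - income_tax - spend
    if np.any(hh_saving < 0):
        raise FixtureError("negative household saving: infeasible income structure")

    # government account
    cap_to_gov = (
        _GOV_TOTAL + transfers.sum() + _GOV_SAVING_TARGET - tariffs.sum() - income_tax.sum()
    )
    if cap_to_gov < 0:
        cap_to_gov = 0.0
    gov_saving = tariffs.sum() + income_tax.sum() + cap_to_gov - _GOV_TOTAL - transfers.sum()
    cap_to_row = yf[6] - cap_to_hh_total - cap_to_gov
    if cap_to_row < 0:
        raise FixtureError("capital income exhausted: infeasible government structure")

    # rest of world: foreign saving is the residual (may be negative)
    fsav = imports.sum() + cap_to_row - exports.sum() - remittances.sum()

    labels = (
        [f"act.{s}" for s in sec]
        + [f"com.{s}" for s in sec]
        + [f"fac.{f}" for f in FACTORS]
        + [f"hh.{h}" for h in HOUSEHOLDS]
        + ["gov", "s-i", "row"]
    )
    ix = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)))

    for j, s in enumerate(sec):
        # activities sell their whole output (domestic + exports) through the
        # commodity account, which also books the export receipt from abroad
        m[ix[f"act.{s}"], ix[f"com.{s}"]] = domestic[j] + exports[j]
        m[ix["row"], ix[f"com.{s}"]] = imports[j]
        m[ix["gov"], ix[f"com.{s}"]] = tariffs[j]
        m[ix[f"com.{s}"], ix["row"]] = exports[j]
        m[ix[f"com.{s}"], ix["gov"]] = gov[j]
        m[ix[f"com.{s}"], ix["s-i"]] = inv[j]
        for i, c in enumerate(sec):
            m[ix[f"com.{c}"], ix[f"act.{s}"]] = qint[i, j]
        for fi, f in enumerate(FACTORS):
            m[ix[f"fac.{f}"], ix[f"act.{s}"]] = fac[fi, j]
    for h_i, h in enumerate(HOUSEHOLDS):
        for j, s in enumerate(sec):
            m[ix[f"com.{s}"], ix[f"hh.{h}"]] = xch[j, h_i]
        for fi, f in enumerate(FACTORS):
            m[ix[f"hh.{h}"], ix[f"fac.{f}"]] = fac2hh[h_i, fi]
        m[ix[f"hh.{h}"], ix["gov"]] = transfers[h_i]
        m[ix[f"hh.{h}"], ix["row"]] = remittances[h_i]
        m[ix["gov"], ix[f"hh.{h}"]] = income_tax[h_i]
        m[ix["s-i"], ix[f"hh.{h}"]] = hh_saving[h_i]
    m[ix["gov"], ix["fac.capital"]] = cap_to_gov
    m[ix["row"], ix["fac.capital"]] = cap_to_row
    m[ix["s-i"], ix["gov"]] = gov_saving
    if fsav >= 0:
        m[ix["s-i"], ix["row"]] = fsav
    else:
        m[ix["row"], ix["s-i"]] = -fsav

    sam = SocialAccountingMatrix(labels, m)
    sam.require_balanced()
    return sam


def _disaggregate(coarse: SocialAccountingMatrix, rng: np.random.Generator) -> SocialAccountingMatrix:
    """Rank-1 split of each coarse sector into its fine children.

    Proportional splitting preserves balance and every within-sector ratio
    (tariff rates, trade shares) exactly.
    """
    weights: dict[str, np.ndarray] = {}
    for s in COARSE_SECTORS:
        k = len(FINE_SECTORS[s])
        w = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.array([1.0])
        weights[s] = w

    fine_labels: list[str] = []
    expand: list[tuple[int, float]] = []  # (coarse index, weight) per fine label
    for i, lab in enumerate(coarse.labels):
        kind = lab.split(".", 1)[0]
        if kind in ("act", "com"):
            s = lab.split(".", 1)[1]
            for f, w in zip(FINE_SECTORS[s], weights[s]):
                fine_labels.append(f"{kind}.{f}")
                expand.append((i, float(w)))
        else:
            fine_labels.append(lab)
            expand.append((i, 1.0))

    nf = len(fine_labels)
    m = np.zeros((nf, nf))
    for i, (ci, wi) in enumerate(expand):
        for j, (cj, wj) in enumerate(expand):
            m[i, j] = coarse.flows[ci, cj] * wi * wj
    sam = SocialAccountingMatrix(fine_labels, m)
    sam.require_balanced()
    return sam


# ---------------------------------------------------------------------------
# Companion fixtures
# ---------------------------------------------------------------------------


@dataclass
class DemandInputs:
    """Per-household AIDS calibration inputs over the coarse commodities."""

    commodities: list[str]
    households: list[str]
    base_shares: np.ndarray          # (H, C)
    income_elasticities: np.ndarray  # (H, C)
    price_elasticities: np.ndarray   # (H, C, C)


_INCOME_ELAST = {
    "primary_food": 0.65, "other_primary": 0.9, "palm_oil": 0.55, "other_oils": 0.6,
    "processed_foods": 0.85, "beverages": 1.05, "manufacturing": 1.15, "services": 1.2,
}
_OWN_PRICE_ELAST = {
    "primary_food": -0.45, "other_primary": -0.6, "palm_oil": -0.5, "other_oils": -0.55,
    "processed_foods": -0.65, "beverages": -0.8, "manufacturing": -0.85, "services": -0.9,
}


def _make_demand_inputs(xch: np.ndarray, rng: np.random.Generator) -> DemandInputs:
    n_c, n_h = xch.shape
    shares = xch / xch.sum(axis=0, keepdims=True)
    eta = np.zeros((n_h, n_c))
    eps = np.zeros((n_h, n_c, n_c))
    for h in range(n_h):
        w = shares[:, h]
        e = np.array([_INCOME_ELAST[s] for s in COARSE_SECTORS])
        e = e * rng.uniform(0.95, 1.05, size=n_c)
        e = e + (1.0 - w @ e)  # exact Engel aggregation
        own = np.array([_OWN_PRICE_ELAST[s] for s in COARSE_SECTORS])
        own = own * rng.uniform(0.95, 1.05, size=n_c)
        mat = np.zeros((n_c, n_c))
        for c in range(n_c):
            mat[c, c] = own[c]
            cross_total = -e[c] - own[c]  # homogeneity: row sums to -eta
            others = np.delete(np.arange(n_c), c)
            ww = w[others] / w[others].sum()
            mat[c, others] = cross_total * ww
        eta[h] = e
        eps[h] = mat
    return DemandInputs(
        commodities=list(COARSE_SECTORS),
        households=list(HOUSEHOLDS),
        base_shares=shares.T.copy(),
        income_elasticities=eta,
        price_elasticities=eps,
    )


_NUTRIENT_BASE = {
    # total energy per currency unit; (sfa, mufa, pufa) fractions of total
    "primary_food": (900.0, 0.04, 0.04, 0.03),
    "other_primary": (0.0, 0.0, 0.0, 0.0),
    "palm_oil": (3000.0, 0.45, 0.35, 0.10),
    "other_oils": (3000.0, 0.15, 0.22, 0.55),
    "processed_foods": (700.0, 0.10, 0.08, 0.05),
    "beverages": (300.0, 0.02, 0.01, 0.01),
    "manufacturing": (0.0, 0.0, 0.0, 0.0),
    "services": (0.0, 0.0, 0.0, 0.0),
}


def _make_nutrients(rng: np.random.Generator) -> dict[str, nutrition.NutrientTable]:
    tables = {}
    for h in HOUSEHOLDS:
        total, sfa, mufa, pufa = [], [], [], []
        for s in COARSE_SECTORS:
            t, fs, fm, fp = _NUTRIENT_BASE[s]
            jitter = rng.uniform(0.95, 1.05)
            t = t * jitter
            total.append(t)
            sfa.append(fs * t)
            mufa.append(fm * t)
            pufa.append(fp * t)
        tables[h] = nutrition.NutrientTable(
            commodities=list(COARSE_SECTORS),
            sfa=np.array(sfa), mufa=np.array(mufa), pufa=np.array(pufa), total=np.array(total),
        )
    return tables


def _make_biomarkers(rng: np.random.Generator) -> dict[str, nutrition.BiomarkerDistribution]:
    out = {}
    for h in HOUSEHOLDS:
        mean = float(rng.normal(4.2, 0.25))
        sd = float(rng.uniform(0.75, 1.0))
        z = (nutrition.BIN_EDGES - mean) / sd
        freq = np.diff(ndtr(z))
        freq = freq / freq.sum()
        out[h] = nutrition.BiomarkerDistribution(mean=mean, freq=freq)
    return out


def _make_risk_params(rng: np.random.Generator) -> pd.DataFrame:
    base_midlife = {
        ("mi_nonfatal", "male"): 0.004, ("mi_nonfatal", "female"): 0.002,
        ("stroke_nonfatal", "male"): 0.003, ("stroke_nonfatal", "female"): 0.0025,
        ("mi_fatal", "male"): 0.002, ("mi_fatal", "female"): 0.001,
        ("stroke_fatal", "male"): 0.0015, ("stroke_fatal", "female"): 0.001,
    }
    log_rr = {"mi_nonfatal": 0.30, "mi_fatal": 0.30, "stroke_nonfatal": 0.18, "stroke_fatal": 0.18}
    rows = []
    for g in clinical.GENDERS:
        for a_ix, a in enumerate(clinical.AGE_GROUPS):
            for loc in clinical.LOCATIONS:
                for ill in clinical.ILLNESSES:
                    if a_ix < 6:  # below age 30: negligible CVD risk
                        rate = 0.0
                    else:
                        rate = base_midlife[(ill, g)] * np.exp(0.33 * (a_ix - 9))
                        rate *= 1.1 if (loc == "urban" and ill.startswith("mi")) else 1.0
                        rate *= float(rng.uniform(0.97, 1.03))
                    rows.append(
                        {"gender": g, "age": a, "location": loc, "illness": ill,
                         "baseline_rate": min(rate, 0.2), "log_rr": log_rr[ill]}
                    )
    return pd.DataFrame(rows)


@dataclass
class DemographyFixture:
    initial: demography.DemographicState
    rates_path: list[demography.VitalRates]   # one per projection year
    planted_ptrans: np.ndarray                # (H, G, A)
    targets: list[np.ndarray]                 # baseline population path


_AGE_WEIGHTS = np.array(
    [0.055, 0.060, 0.065, 0.070, 0.075, 0.080, 0.080, 0.080,
     0.075, 0.070, 0.065, 0.060, 0.050, 0.040, 0.075]
)
_ASFR = np.array([0.020, 0.050, 0.070, 0.060, 0.030, 0.010, 0.002])


def _make_demography(rng: np.random.Generator, years: int) -> DemographyFixture:
    n_h, n_g, n_a = len(HOUSEHOLDS), len(clinical.GENDERS), demography.N_AGES
    total = 67_000.0  # thousands of persons
    hw = _HH_POP_WEIGHTS / _HH_POP_WEIGHTS.sum()
    aw = _AGE_WEIGHTS / _AGE_WEIGHTS.sum()
    gw = np.array([0.49, 0.51])
    pop = total * hw[:, None, None] * gw[None, :, None] * aw[None, None, :]
    pop *= rng.uniform(0.97, 1.03, size=pop.shape)
    initial = demography.DemographicState([f"hh.{h}" for h in HOUSEHOLDS], pop, year=2015)

    age_ix = np.arange(n_a)
    mu_age = 0.0004 * np.exp(0.33 * age_ix)
    mu_age[0] += 0.004
    mortality = np.zeros((n_h, n_g, n_a))
    mortality[:, 0, :] = mu_age * 1.2
    mortality[:, 1, :] = mu_age
    mortality *= rng.uniform(0.95, 1.05, size=mortality.shape)

    migration = np.zeros((n_h, n_g, n_a))
    for h_i, h in enumerate(HOUSEHOLDS):
        migration[h_i] = 0.0006 if h.endswith("_rural") else 0.0002

    asfr = np.zeros(n_a)
    asfr[demography.FERTILE] = _ASFR
    ptrans = np.full((n_h, n_g, n_a), 0.2)
    base_rates = demography.VitalRates(
        sexratio=np.array([0.512, 0.488]),
        asfr=asfr,
        mortality=mortality,
        migration=migration,
        ptrans=ptrans,
    )
    rates_path = [base_rates for _ in range(years)]

    targets = []
    state = initial.copy()
    for rates in rates_path:
        state = demography.project_year(state, rates)
        targets.append(state.pop.copy())
    return DemographyFixture(
        initial=initial, rates_path=rates_path, planted_ptrans=ptrans, targets=targets
    )


def _make_healthecon(rng: np.random.Generator) -> feedbacks.HealthEconParams:
    skill = np.zeros((len(HOUSEHOLDS), 2))
    for h_i, h in enumerate(HOUSEHOLDS):
        unsk = 0.55 if (h == "bangkok" or h.endswith("_urban")) else 0.8
        unsk *= float(rng.uniform(0.97, 1.03))
        skill[h_i] = (unsk, 1.0 - unsk)
    return feedbacks.HealthEconParams(
        caregiver_work={"mi_nonfatal": 0.10, "stroke_nonfatal": 0.15},
        caregiver_leisure={"mi_nonfatal": 0.15, "stroke_nonfatal": 0.25},
        illness_duration={"mi_nonfatal": 28.0 / 365.0, "stroke_nonfatal": 1.0},
        yld_weight={"mi_nonfatal": 0.12, "stroke_nonfatal": 0.27},
        participation={"male": 0.80, "female": 0.65},
        skill_share=skill,
        huc0={
            "mi_nonfatal": np.array([5e-5, 0.0, 0.0, 0.0]),
            "stroke_nonfatal": np.array([8e-5, 4e-5, 2e-5, 1e-5]),
            "mi_fatal": np.zeros(4),
            "stroke_fatal": np.zeros(4),
        },
        public_share=0.8,
    )


_CARBON_STOCKS = {"primary_food": 1.5, "other_primary": 4.0}


def _make_emissions() -> luc.EmissionMatrix:
    acts = list(AGRICULTURAL_SECTORS)
    stocks = np.array([_CARBON_STOCKS[a] for a in acts])
    # Mt CO2-eq per land-value unit, scaled to yield Mt-order scenario impacts
    return luc.EmissionMatrix.from_carbon_stocks(acts, stocks * 0.02)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    """Everything the simulation pipeline needs, generated from one seed."""

    seed: int
    targets: Table1Shares
    sam: SocialAccountingMatrix            # fine, 49 sectors
    smap: SectorMap
    demand: DemandInputs
    nutrients: dict[str, nutrition.NutrientTable]
    chol_response: nutrition.CholesterolResponse
    biomarkers: dict[str, nutrition.BiomarkerDistribution]
    risk_params: pd.DataFrame
    lookup: clinical.ClinicalLookup
    demog: DemographyFixture
    healthecon: feedbacks.HealthEconParams
    emissions: luc.EmissionMatrix
    horizon: tuple[int, int] = (2016, 2035)
    manifest: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sam.write_csv(out / "sam.csv")
        self.smap.to_frame().to_csv(out / "sector_map.csv", index=False)
        self.targets.to_frame().to_csv(out / "targets.csv", index=False)

        d = self.demand
        pd.DataFrame(d.base_shares, index=d.households, columns=d.commodities).to_csv(
            out / "demand_base_shares.csv"
        )
        pd.DataFrame(
            d.income_elasticities, index=d.households, columns=d.commodities
        ).to_csv(out / "demand_income_elasticities.csv")
        rows = []
        for h_i, h in enumerate(d.households):
            for c_i, c in enumerate(d.commodities):
                for c2_i, c2 in enumerate(d.commodities):
                    rows.append(
                        {"household": h, "commodity": c, "commodity_prime": c2,
                         "value": d.price_elasticities[h_i, c_i, c2_i]}
                    )
        pd.DataFrame(rows).to_csv(out / "demand_price_elasticities.csv", index=False)

        nut_rows = []
        for h, tbl in self.nutrients.items():
            for c_i, c in enumerate(tbl.commodities):
                nut_rows.append(
                    {"household": h, "commodity": c, "sfa": tbl.sfa[c_i],
                     "mufa": tbl.mufa[c_i], "pufa": tbl.pufa[c_i], "total": tbl.total[c_i]}
                )
        pd.DataFrame(nut_rows).to_csv(out / "nutrients.csv", index=False)
        pd.DataFrame(
            [{"c_sfa": self.chol_response.c_sfa, "c_mufa": self.chol_response.c_mufa,
              "c_pufa": self.chol_response.c_pufa, "mufa_term": self.chol_response.mufa_term}]
        ).to_csv(out / "chol_response.csv", index=False)

        bio_rows = []
        for h, dist in self.biomarkers.items():
            for s_i in range(nutrition.N_STRATA):
                bio_rows.append(
                    {"household": h, "stratum": s_i, "mean": dist.mean,
                     "freq": dist.freq[s_i], "value": dist.values[s_i]}
                )
        pd.DataFrame(bio_rows).to_csv(out / "biomarkers.csv", index=False)

        self.risk_params.to_csv(out / "clinical_risk_params.csv", index=False)
        self.lookup.to_frame().to_csv(out / "clinical_lookup.csv", index=False)
        self.emissions.to_frame().to_csv(out / "luc_coefficients.csv", index=False)

        demog_rows = []
        for h_i, h in enumerate(self.demog.initial.households):
            for g_i, g in enumerate(clinical.GENDERS):
                for a_i, a in enumerate(clinical.AGE_GROUPS):
                    demog_rows.append(
                        {"household": h, "gender": g, "age": a,
                         "pop": self.demog.initial.pop[h_i, g_i, a_i]}
                    )
        pd.DataFrame(demog_rows).to_csv(out / "population.csv", index=False)

        manifest = {
            "seed": self.seed,
            "horizon": list(self.horizon),
            "targets": self.targets.to_frame().to_dict(orient="list"),
            "checksums": {},
        }
        for f in sorted(out.glob("*.csv")):
            manifest["checksums"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_fixtures(seed: int = DEFAULT_SEED, targets: Table1Shares | None = None) -> FixtureBundle:
    """Generate the full synthetic fixture bundle, a pure function of (seed, targets)."""
    if targets is None:
        targets = default_targets()
    rng = np.random.default_rng(seed)
    coarse = _build_coarse_sam(rng, targets)
    fine = _disaggregate(coarse, rng)

    frame = coarse.to_frame()
    xch = frame.loc[
        [f"com.{s}" for s in COARSE_SECTORS], [f"hh.{h}" for h in HOUSEHOLDS]
    ].to_numpy()
    demand_inputs = _make_demand_inputs(xch, rng)
    nutrients = _make_nutrients(rng)
    biomarkers = _make_biomarkers(rng)
    risk_params = _make_risk_params(rng)
    lookup = clinical.generate_lookup(seed, risk_params)
    horizon = (2016, 2035)
    demog = _make_demography(rng, years=horizon[1] - horizon[0] + 1)
    healthecon = _make_healthecon(rng)
    emissions = _make_emissions()
    return FixtureBundle(
        seed=seed,
        targets=targets,
        sam=fine,
        smap=sector_map(),
        demand=demand_inputs,
        nutrients=nutrients,
        chol_response=nutrition.CholesterolResponse(c_sfa=0.30, c_mufa=-0.60, c_pufa=-1.20),
        biomarkers=biomarkers,
        risk_params=risk_params,
        lookup=lookup,
        demog=demog,
        healthecon=healthecon,
        emissions=emissions,
        horizon=horizon,
    )
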