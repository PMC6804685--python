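"""Stratified clinical CVD outcome rates from polynomial lookups, and levels.

A degree-10 polynomial in the cholesterol biomarker is stored per
(gender, age group, location, illness).  Rates are evaluated at each biomarker
stratum's representative value and converted to incident-case / death levels by
mixing over strata frequencies and multiplying by population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .nutrition import BIOMARKER_HI, BIOMARKER_LO, BiomarkerDistribution

GENDERS = ["male", "female"]
AGE_GROUPS = [
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70+",
]
LOCATIONS = ["rural", "urban"]
ILLNESSES = ["mi_nonfatal", "stroke_nonfatal", "mi_fatal", "stroke_fatal"]
NONFATAL = ["mi_nonfatal", "stroke_nonfatal"]
FATAL = ["mi_fatal", "stroke_fatal"]
POLY_DEGREE = 10

#: Biomarker value at which the baseline rate applies in the hazard model.
REFERENCE_BIOMARKER = 4.5


class ClinicalError(ValueError):
    pass


@dataclass
class ClinicalLookup:
    """Polynomial rate coefficients, indexed [gender, age, location, illness, degree]."""

    coef: np.ndarray  # shape (2, 15, 2, 4, 11)

    def __post_init__(self) -> None:
        expected = (len(GENDERS), len(AGE_GROUPS), len(LOCATIONS), len(ILLNESSES), POLY_DEGREE + 1)
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.shape != expected:
            raise ClinicalError(f"lookup tensor must have shape {expected}")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [GENDERS, AGE_GROUPS, LOCATIONS, ILLNESSES, range(POLY_DEGREE + 1)],
            names=["gender", "age", "location", "illness", "degree"],
        )
        return pd.DataFrame({"coef": self.coef.ravel()}, index=idx).reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClinicalLookup":
        shape = (len(GENDERS), len(AGE_GROUPS), len(LOCATIONS), len(ILLNESSES), POLY_DEGREE + 1)
        coef = np.zeros(shape)
        g_ix = {g: i for i, g in enumerate(GENDERS)}
        a_ix = {a: i for i, a in enumerate(AGE_GROUPS)}
        l_ix = {l: i for i, l in enumerate(LOCATIONS)}
        i_ix = {i: k for k, i in enumerate(ILLNESSES)}
        for row in frame.itertuples():
            coef[g_ix[row.gender], a_ix[row.age], l_ix[row.location], i_ix[row.illness], row.degree] = row.coef
        return cls(coef)


def evaluate_poly(coef: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Horner evaluation of polynomials whose last axis is the degree."""
    x = np.asarray(x, dtype=float)
    out = np.broadcast_to(coef[..., -1][..., np.newaxis], coef.shape[:-1] + x.shape).copy()
    for r in range(POLY_DEGREE - 1, -1, -1):
        out = out * x + coef[..., r, np.newaxis]
    return out


def generate_lookup(seed: int, risk_params: pd.DataFrame) -> ClinicalLookup:
    """Fit degree-10 polynomials to a logistic biomarker-hazard model.

    ``risk_params`` must contain one row per (gender, age, location, illness)
    with columns ``baseline_rate`` (annual event rate at the reference
    biomarker) and ``log_rr`` (log relative risk per unit biomarker, >= 0 so
    rates are non-decreasing).  Each surface is evaluated on a grid over
    [2.0, 7.0] and fitted with a polynomial; the fit is verified on a
    1001-point grid (max abs error <= 1e-6, rates within [0, 1],
    non-decreasing).

    ``seed`` is accepted for interface uniformity with the other fixture
    generators; the fit itself is deterministic given ``risk_params``.
    """
    del seed  # deterministic given risk_params
    shape = (len(GENDERS), len(AGE_GROUPS), len(LOCATIONS), len(ILLNESSES), POLY_DEGREE + 1)
    coef = np.zeros(shape)
    fit_grid = np.linspace(BIOMARKER_LO, BIOMARKER_HI, 201)
    check_grid = np.linspace(BIOMARKER_LO, BIOMARKER_HI, 1001)
    g_ix = {g: i for i, g in enumerate(GENDERS)}
    a_ix = {a: i for i, a in enumerate(AGE_GROUPS)}
    l_ix = {l: i for i, l in enumerate(LOCATIONS)}
    i_ix = {i: k for k, i in enumerate(ILLNESSES)}
    required = {"gender", "age", "location", "illness", "baseline_rate", "log_rr"}
    if not required.issubset(risk_params.columns):
        raise ClinicalError(f"risk_params needs columns {sorted(required)}")
    for row in risk_params.itertuples():
        b = float(row.baseline_rate)
        lrr = float(row.log_rr)
        if not 0.0 <= b < 1.0:
            raise ClinicalError(f"baseline rate {b} outside [0, 1)")
        if lrr < 0:
            raise ClinicalError("log relative risk must be non-negative")
        if b == 0.0 or lrr == 0.0:
            # Flat surface: constant polynomial.
            c = np.zeros(POLY_DEGREE + 1)
            c[0] = b
        else:
            y = expit(logit(b) + lrr * (fit_grid - REFERENCE_BIOMARKER))
            # Fit on a scaled domain for conditioning, then convert to raw
            # power-basis coefficients beta * chol^r.
            poly = np.polynomial.Polynomial.fit(fit_grid, y, POLY_DEGREE)
            c = poly.convert().coef
            c = np.pad(c, (0, POLY_DEGREE + 1 - c.size))
        pred = evaluate_poly(c, check_grid)
        target = (
            expit(logit(b) + lrr * (check_grid - REFERENCE_BIOMARKER))
            if (b > 0 and lrr > 0)
            else np.full_like(check_grid, b)
        )
        err = float(np.max(np.abs(pred - target)))
        if err > 1e-6:
            raise ClinicalError(f"polynomial fit error {err:.2e} exceeds 1e-6 for {row}")
        if np.any(pred < -1e-12) or np.any(pred > 1.0):
            raise ClinicalError("fitted rates leave [0, 1]")
        if np.any(np.diff(pred) < -1e-9):
            raise ClinicalError("fitted rates not non-decreasing in the biomarker")
        coef[g_ix[row.gender], a_ix[row.age], l_ix[row.location], i_ix[row.illness]] = c
    return ClinicalLookup(coef)


def household_location(household: str) -> str:
    """Resolve a household label to its rural/urban location class."""
    name = household.split(".", 1)[-1]
    if name.endswith("_rural"):
        return "rural"
    return "urban"  # urban households and the capital


def rates(lookup: ClinicalLookup, dist: BiomarkerDistribution, household: str) -> np.ndarray:
    """Stratified outcome rates, shape (n_strata, gender, age, illness).

    The household's rural/urban class selects the location slice; rates are a
    Horner evaluation of the lookup polynomials at each stratum's
    representative biomarker value.
    """
    values = np.asarray(dist.values, dtype=float)
    if np.any(values < BIOMARKER_LO - 1e-9) or np.any(values > BIOMARKER_HI + 1e-9):
        raise ClinicalError("biomarker value outside [2.0, 7.0] reached the lookup")
    loc = LOCATIONS.index(household_location(household))
    c = lookup.coef[:, :, loc, :, :]  # (gender, age, illness, degree)
    out = evaluate_poly(c, values)  # (gender, age, illness, strata)
    return np.clip(np.moveaxis(out, -1, 0), 0.0, 1.0)


@dataclass
class ClinicalOutcome:
    """Per-household stratified rates and population-scaled outcome levels."""

    household: str
    rates: np.ndarray   # (strata, gender, age, illness)
    levels: np.ndarray  # (gender, age, illness), persons/year


def levels(
    strat_rates: np.ndarray, dist: BiomarkerDistribution, pop: np.ndarray, household: str = ""
) -> ClinicalOutcome:
    """Outcome levels = sum_s freq_s * rate_s * POP, per (gender, age, illness)."""
    pop = np.asarray(pop, dtype=float)
    if np.any(pop < 0):
        raise ClinicalError("negative population")
    freq = dist.freq
    if abs(freq.sum() - 1.0) > 1e-9:
        raise ClinicalError("strata frequencies must sum to 1")
    mixed = np.tensordot(freq, strat_rates, axes=(0, 0))  # (gender, age, illness)
    lev = mixed * pop[:, :, None]
    return ClinicalOutcome(household=household, rates=strat_rates, levels=lev)
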