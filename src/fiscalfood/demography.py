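"""Cohort-component population projection with mortality feedback.

Populations are stored as arrays indexed [household, gender, age group] with
15 five-year age groups (0-4 ... 65-69, 70+) advanced on an annual time step
via calibrated transition probabilities.  The within-year ordering is:
survive (1 - mu), then remain (1 - migration), then age-group transition;
births enter the youngest group; the terminal group accumulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clinical import AGE_GROUPS, GENDERS

logger = logging.getLogger(__name__)

N_AGES = len(AGE_GROUPS)
FEMALE = GENDERS.index("female")
#: Age-group indices covering fertile ages 15-49.
FERTILE = slice(3, 10)
#: Age-group indices covering working ages 15-64.
WORKING = slice(3, 13)


class DemographyError(ValueError):
    pass


@dataclass
class DemographicState:
    """Population counts by household x gender x age group at one point in time."""

    households: list[str]
    pop: np.ndarray  # (H, G, A)
    year: int = 0

    def __post_init__(self) -> None:
        self.pop = np.asarray(self.pop, dtype=float)
        expected = (len(self.households), len(GENDERS), N_AGES)
        if self.pop.shape != expected:
            raise DemographyError(f"population array must have shape {expected}")
        if np.any(self.pop < 0):
            raise DemographyError("negative population")

    @property
    def total(self) -> float:
        return float(self.pop.sum())

    def copy(self) -> "DemographicState":
        return DemographicState(list(self.households), self.pop.copy(), self.year)


@dataclass
class VitalRates:
    """Vital rates for one projection year.

    sexratio : shares of births by sex (sums to 1)
    asfr     : fertility rates per fertile age group (length-A, zero outside 15-49)
    mortality: all-cause mortality rates, (H, G, A)
    migration: net emigration rates, (H, G, A)
    ptrans   : age-group transition probabilities, (H, G, A); the terminal
               group's value is unused for exit.
    """

    sexratio: np.ndarray
    asfr: np.ndarray
    mortality: np.ndarray
    migration: np.ndarray
    ptrans: np.ndarray

    def __post_init__(self) -> None:
        self.sexratio = np.asarray(self.sexratio, dtype=float)
        self.asfr = np.asarray(self.asfr, dtype=float)
        for name in ("mortality", "migration", "ptrans"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr < 0) or np.any(arr > 1):
                raise DemographyError(f"{name} rates outside [0, 1]")
        if abs(self.sexratio.sum() - 1.0) > 1e-9:
            raise DemographyError("sex ratio shares must sum to 1")


def project_year(state: DemographicState, rates: VitalRates) -> DemographicState:
    """Advance the population one year (births, deaths, migration, aging)."""
    pop = state.pop
    mu = rates.mortality
    mig = rates.migration
    p = rates.ptrans

    survivors = (1.0 - mig) * (1.0 - mu) * pop  # (H, G, A)

    births_by_mother = (rates.asfr[FERTILE] * pop[:, FEMALE, FERTILE]).sum(axis=1)  # (H,)
    births = births_by_mother[:, None] * rates.sexratio[None, :]  # (H, G)

    new = np.empty_like(pop)
    new[:, :, 0] = (1.0 - p[:, :, 0]) * survivors[:, :, 0] + births
    for a in range(1, N_AGES - 1):
        new[:, :, a] = (
            p[:, :, a - 1] * survivors[:, :, a - 1]
            + (1.0 - p[:, :, a]) * survivors[:, :, a]
        )
    new[:, :, -1] = p[:, :, -2] * survivors[:, :, -2] + survivors[:, :, -1]
    return DemographicState(list(state.households), new, state.year + 1)


def vital_events(state: DemographicState, rates: VitalRates) -> tuple[np.ndarray, np.ndarray]:
    """Deaths and net emigration implied by one projection step."""
    deaths = rates.mortality * state.pop
    migr = rates.migration * (1.0 - rates.mortality) * state.pop
    return deaths, migr


def calibrate_transitions(
    initial: DemographicState,
    targets: list[np.ndarray],
    rates_path: list[VitalRates],
    rtol: float = 1e-6,
) -> list[np.ndarray]:
    """Recover year-specific transition probabilities hitting a target path.

    For each year the transition probabilities are solved sequentially from the
    youngest group (each group's target pins the probability of leaving it,
    given the inflow already determined from the group below).  The terminal
    group has no free parameter; its implied population must match the target
    within ``rtol`` or the path is infeasible.

    Values falling outside [0, 1] are clamped and logged as violations.

    Returns the list of (H, G, A) transition arrays, one per target year.
    """
    state = initial.copy()
    out: list[np.ndarray] = []
    for t, (target, rates) in enumerate(zip(targets, rates_path)):
        pop = state.pop
        survivors = (1.0 - rates.migration) * (1.0 - rates.mortality) * pop
        births_by_mother = (rates.asfr[FERTILE] * pop[:, FEMALE, FERTILE]).sum(axis=1)
        births = births_by_mother[:, None] * rates.sexratio[None, :]

        p = np.zeros_like(pop)
        scale = max(float(target.max()), 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            s0 = survivors[:, :, 0]
            stay0 = target[:, :, 0] - births
            p[:, :, 0] = np.where(s0 > 0, 1.0 - stay0 / np.where(s0 > 0, s0, 1.0), 0.0)
            for a in range(1, N_AGES - 1):
                inflow = p[:, :, a - 1] * survivors[:, :, a - 1]
                sa = survivors[:, :, a]
                stay = target[:, :, a] - inflow
                p[:, :, a] = np.where(sa > 0, 1.0 - stay / np.where(sa > 0, sa, 1.0), 0.0)
        # Terminal-group consistency check (no free parameter left).
        implied_term = p[:, :, -2] * survivors[:, :, -2] + survivors[:, :, -1]
        term_err = float(np.max(np.abs(implied_term - target[:, :, -1]))) / scale
        if term_err > rtol:
            raise DemographyError(
                f"target path infeasible in year {t}: terminal-group residual {term_err:.3g}"
            )
        if np.any(p < -rtol) or np.any(p > 1 + rtol):
            raise DemographyError(
                f"target path requires transition probability outside [0, 1] in year {t}"
            )
        clipped = np.clip(p, 0.0, 1.0)
        if np.any(clipped != p):
            logger.warning("transition probabilities clamped to [0, 1] in year %d", t)
        out.append(clipped)
        cal = VitalRates(rates.sexratio, rates.asfr, rates.mortality, rates.migration, clipped)
        state = project_year(state, cal)
    return out


def apply_excess_feedback(
    mu_count: np.ndarray, excess_policy: np.ndarray, excess_count: np.ndarray
) -> np.ndarray:
    """Policy all-cause mortality = counterfactual + sum of excess-rate deltas.

    ``excess_*`` have an illness axis last; the delta is summed over it.
    Results are clamped to [0, 1] with a logged warning when clamping occurs.
    """
    if excess_policy.shape != excess_count.shape:
        raise DemographyError("excess mortality arrays must have matching shapes")
    adjusted = mu_count + (excess_policy - excess_count).sum(axis=-1)
    if np.any(adjusted < 0) or np.any(adjusted > 1):
        logger.warning("all-cause mortality clamped to [0, 1] after excess feedback")
        adjusted = np.clip(adjusted, 0.0, 1.0)
    return adjusted


def excess_mortality(freq: np.ndarray, fatal_rates: np.ndarray) -> np.ndarray:
    """Strata-frequency-weighted fatal outcome rates, (gender, age, illness)."""
    return np.tensordot(freq, fatal_rates, axes=(0, 0))
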