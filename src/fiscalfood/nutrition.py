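"""Fatty-acid intake shares, cholesterol biomarker response, and strata shifting."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Biomarker domain (Total:HDL serum cholesterol ratio) and strata layout.
BIOMARKER_LO = 2.0
BIOMARKER_HI = 7.0
N_STRATA = 10
BIN_EDGES = np.linspace(BIOMARKER_LO, BIOMARKER_HI, N_STRATA + 1)
BIN_MIDPOINTS = 0.5 * (BIN_EDGES[:-1] + BIN_EDGES[1:])


class NutritionError(ValueError):
    pass


@dataclass
class NutrientTable:
    """Energy coefficients per commodity: fatty-acid and total energy content.

    All coefficients are energy per unit of consumption; the fatty-acid
    contents cannot exceed the total.
    """

    commodities: list[str]
    sfa: np.ndarray
    mufa: np.ndarray
    pufa: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sfa", "mufa", "pufa", "total"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if np.any(getattr(self, name) < 0):
                raise NutritionError(f"negative {name} energy coefficient")
        if np.any(self.sfa + self.mufa + self.pufa > self.total * (1 + 1e-12)):
            raise NutritionError("fatty-acid energy exceeds total energy")


def intake_shares(x: np.ndarray, nutrients: NutrientTable) -> tuple[float, float, float]:
    """SFA/MUFA/PUFA energy-intake shares of the consumption vector ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise NutritionError("negative consumption")
    energy = float(nutrients.total @ x)
    if energy <= 0:
        raise NutritionError("total energy intake is zero")
    return (
        float(nutrients.sfa @ x) / energy,
        float(nutrients.mufa @ x) / energy,
        float(nutrients.pufa @ x) / energy,
    )


@dataclass(frozen=True)
class CholesterolResponse:
    """Biomarker build-up coefficients per unit change of energy-intake share."""

    c_sfa: float
    c_mufa: float
    c_pufa: float
    #: 'ratio' applies the MUFA coefficient weighted by the MUFA share of total
    #: fatty-acid energy; 'linear' applies it directly.
    mufa_term: str = "ratio"

    def __post_init__(self) -> None:
        if self.mufa_term not in ("ratio", "linear"):
            raise NutritionError(f"unknown mufa_term {self.mufa_term!r}")
        if not all(np.isfinite([self.c_sfa, self.c_mufa, self.c_pufa])):
            raise NutritionError("non-finite response coefficient")


def cholesterol_delta(
    d_sfa: float,
    d_mufa: float,
    d_pufa: float,
    levels: tuple[float, float, float],
    resp: CholesterolResponse,
) -> float:
    """Biomarker change from intake-share changes.

    ``levels`` are the current (e_SFA, e_MUFA, e_PUFA) shares, used for the
    MUFA ratio weighting e_MUFA / (e_SFA + e_MUFA + e_PUFA).
    """
    e_sfa, e_mufa, e_pufa = levels
    if resp.mufa_term == "ratio":
        e_fat = e_sfa + e_mufa + e_pufa
        mufa_weight = e_mufa / e_fat if e_fat > 0 else 0.0
    else:
        mufa_weight = 1.0
    return resp.c_sfa * d_sfa + resp.c_mufa * mufa_weight * d_mufa + resp.c_pufa * d_pufa


@dataclass
class BiomarkerDistribution:
    """Mean biomarker plus a 10-bin strata distribution on [2.0, 7.0]."""

    mean: float
    freq: np.ndarray
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.size != N_STRATA:
            raise NutritionError(f"expected {N_STRATA} strata frequencies")
        if np.any(self.freq < 0) or abs(self.freq.sum() - 1.0) > 1e-9:
            raise NutritionError("frequencies must be non-negative and sum to 1")
        if self.values is None:
            self.values = BIN_MIDPOINTS.copy()
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.size != N_STRATA:
                raise NutritionError(f"expected {N_STRATA} strata values")
        if not (BIOMARKER_LO <= self.mean <= BIOMARKER_HI):
            raise NutritionError("mean biomarker outside [2.0, 7.0]")


def shift_distribution(dist: BiomarkerDistribution, delta: float) -> BiomarkerDistribution:
    """Shift every stratum's representative value (and the mean) by ``delta``.

    Values are clamped to the biomarker domain; frequencies are untouched, so
    probability mass is conserved.
    """
    if not np.isfinite(delta):
        raise NutritionError("non-finite biomarker shift")
    return replace(
        dist,
        mean=float(np.clip(dist.mean + delta, BIOMARKER_LO, BIOMARKER_HI)),
        freq=dist.freq.copy(),
        values=np.clip(dist.values + delta, BIOMARKER_LO, BIOMARKER_HI),
    )
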