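"""Land-use-change accounting: crop transition flows and GHG emission changes.

Year-on-year land reallocations across agricultural activities are pooled per
regional land factor: total gains equal total losses (land supplies are fixed),
and each loss activity's hectares flow to each gain activity in proportion to
the gain shares.  An antisymmetric per-hectare emission matrix converts the
bilateral flows into a CO2-equivalent emission change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LAND_REGIONS = ["central_east", "north", "northeast", "south"]


class LucError(ValueError):
    pass


@dataclass
class LandAllocation:
    """Land use per agricultural activity x regional land factor (hectare units)."""

    activities: list[str]
    area: np.ndarray  # (act, region)

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if self.area.shape != (len(self.activities), len(LAND_REGIONS)):
            raise LucError(
                f"area must have shape ({len(self.activities)}, {len(LAND_REGIONS)})"
            )

    @property
    def regional_totals(self) -> np.ndarray:
        return self.area.sum(axis=0)


@dataclass
class EmissionMatrix:
    """Per-hectare GHG emission coefficients for activity transitions (Mt CO2-eq/ha)."""

    activities: list[str]
    coef: np.ndarray  # (act, act), antisymmetric

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        n = len(self.activities)
        if self.coef.shape != (n, n):
            raise LucError("coefficient matrix must be square over activities")
        if np.max(np.abs(self.coef + self.coef.T)) > 1e-9:
            raise LucError("emission coefficients must be antisymmetric")

    @classmethod
    def from_carbon_stocks(cls, activities: list[str], stocks: np.ndarray) -> "EmissionMatrix":
        """Build coefficients from per-crop carbon-stock scalars.

        A transition a1 -> a2 releases stock(a1) - stock(a2) per hectare,
        guaranteeing antisymmetry and a zero diagonal.
        """
        s = np.asarray(stocks, dtype=float)
        return cls(activities, s[:, None] - s[None, :])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a1 in enumerate(self.activities):
            for j, a2 in enumerate(self.activities):
                rows.append({"act_from": a1, "act_to": a2, "coef": self.coef[i, j]})
        return pd.DataFrame(rows)


@dataclass
class TransitionFlows:
    """Bilateral hectare flows act1 -> act2 per region for one year."""

    activities: list[str]
    flows: np.ndarray  # (act_from, act_to, region), >= 0

    @property
    def total_positive_change(self) -> np.ndarray:
        return self.flows.sum(axis=(0, 1))


def transitions(prev: LandAllocation, curr: LandAllocation, rtol: float = 1e-7) -> TransitionFlows:
    """Bilateral transition flows between two consecutive land allocations.

    Positive changes per region are pooled; activities are split into gain
    (change > 0) and loss (change <= 0) sets; each bilateral flow is
    loss share x gain share x pooled change.  Regional land totals must be
    conserved between the two allocations.
    """
    if prev.activities != curr.activities:
        raise LucError("allocations cover different activity sets")
    scale = np.maximum(prev.regional_totals, 1e-300)
    if np.any(np.abs(curr.regional_totals - prev.regional_totals) > rtol * scale):
        raise LucError("regional land totals not conserved between years")
    delta = curr.area - prev.area  # (act, region)
    gain_mask = delta > 0
    pos = np.where(gain_mask, delta, 0.0)
    neg = np.where(~gain_mask, np.abs(delta), 0.0)
    pooled = pos.sum(axis=0)  # (region,)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe = np.where(pooled > 0, pooled, 1.0)
        gain_share = np.where(pooled > 0, pos / safe, 0.0)
        loss_share = np.where(pooled > 0, neg / safe, 0.0)
    flows = loss_share[:, None, :] * gain_share[None, :, :] * pooled[None, None, :]
    return TransitionFlows(list(prev.activities), flows)


def ghg_delta(flows: TransitionFlows, coef: EmissionMatrix) -> float:
    """Emission change (Mt CO2-eq) implied by one year's transition flows."""
    if flows.activities != coef.activities:
        raise LucError("flows and coefficients cover different activity sets")
    return float(np.einsum("ij,ijr->", coef.coef, flows.flows))
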