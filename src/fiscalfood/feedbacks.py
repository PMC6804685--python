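"""Labour-supply and health-cost feedbacks from clinical outcomes to the economy."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clinical import FATAL, GENDERS, ILLNESSES, NONFATAL
from .demography import WORKING

LABOUR_TYPES = ["unskilled", "skilled"]
N_LAGS = 4


class FeedbackError(ValueError):
    pass


@dataclass
class HealthEconParams:
    """Health-economic parameters shared by all households.

    caregiver_work / caregiver_leisure : time-loss rates per case-year, per illness
    illness_duration : years per episode (non-fatal MI is 28/365)
    yld_weight : disability weights per illness
    participation : labour-force participation rate per gender
    skill_share : (H, 2) household composition over unskilled/skilled labour
    huc0 : base-year health unit costs per illness x lag (lags 1-3 are only
           non-zero for non-fatal stroke)
    public_share : publicly funded share of excess health costs
    patient_illnesses : illnesses carrying patient worktime losses; the default
        follows the morbidity (non-fatal) interpretation, the as-written fatal
        indexing is available by passing the fatal pair.
    """

    caregiver_work: dict[str, float]
    caregiver_leisure: dict[str, float]
    illness_duration: dict[str, float]
    yld_weight: dict[str, float]
    participation: dict[str, float]
    skill_share: np.ndarray
    huc0: dict[str, np.ndarray]
    public_share: float = 0.8
    patient_illnesses: tuple[str, ...] = tuple(NONFATAL)

    def __post_init__(self) -> None:
        self.skill_share = np.asarray(self.skill_share, dtype=float)
        if np.any(self.skill_share < 0) or np.any(
            np.abs(self.skill_share.sum(axis=1) - 1.0) > 1e-9
        ):
            raise FeedbackError("skill shares must be non-negative and sum to 1 per household")
        for g, r in self.participation.items():
            if not 0.0 <= r <= 1.0:
                raise FeedbackError(f"participation rate for {g} outside [0, 1]")
        if not 0.0 <= self.public_share <= 1.0:
            raise FeedbackError("public share outside [0, 1]")
        for i in ILLNESSES:
            arr = np.asarray(self.huc0.get(i, np.zeros(N_LAGS)), dtype=float)
            if arr.size != N_LAGS:
                raise FeedbackError(f"huc0[{i}] must cover lags 0..{N_LAGS - 1}")
            self.huc0[i] = arr
        if np.any(self.huc0.get("mi_nonfatal", np.zeros(N_LAGS))[1:] != 0):
            raise FeedbackError("lagged unit costs must be zero for non-fatal MI")


@dataclass
class TimeLosses:
    """Person-year losses per household x non-fatal illness, plus YLD by gender."""

    households: list[str]
    caregiver_work: np.ndarray    # (H, n_nonfatal)
    caregiver_leisure: np.ndarray
    yld: np.ndarray               # (H, G, n_nonfatal)
    patient_work: np.ndarray      # (H, n_nonfatal)

    def zeroed(self) -> "TimeLosses":
        return TimeLosses(
            self.households,
            np.zeros_like(self.caregiver_work),
            np.zeros_like(self.caregiver_leisure),
            np.zeros_like(self.yld),
            np.zeros_like(self.patient_work),
        )


def time_losses(levels_by_household: np.ndarray, households: list[str],
                params: HealthEconParams) -> TimeLosses:
    """Caregiver/patient time losses and YLD from non-fatal outcome levels.

    ``levels_by_household`` has shape (H, G, A, illness) over all four
    illnesses; only the non-fatal pair generates losses.
    """
    if np.any(levels_by_household < 0):
        raise FeedbackError("negative outcome levels")
    ill_ix = [ILLNESSES.index(i) for i in NONFATAL]
    nf = levels_by_household[:, :, :, ill_ix]  # (H, G, A, 2)
    total_cases = nf.sum(axis=(1, 2))          # (H, 2)
    by_gender = nf.sum(axis=2)                 # (H, G, 2)

    dur = np.array([params.illness_duration[i] for i in NONFATAL])
    cw = np.array([params.caregiver_work[i] for i in NONFATAL])
    cl = np.array([params.caregiver_leisure[i] for i in NONFATAL])
    ylw = np.array([params.yld_weight[i] for i in NONFATAL])
    part = np.array([params.participation[g] for g in GENDERS])

    care_work = cw * dur * total_cases
    care_leisure = cl * dur * total_cases
    yld = ylw * dur * by_gender                # (H, G, 2)

    if tuple(params.patient_illnesses) == tuple(NONFATAL):
        yld_for_patient = yld
    else:
        # As-written indexing over the fatal pair: fatal levels with the
        # non-fatal YLD machinery.
        fat_ix = [ILLNESSES.index(i) for i in FATAL]
        yld_for_patient = ylw * dur * levels_by_household[:, :, :, fat_ix].sum(axis=2)
    patient_work = np.einsum("g,hgi->hi", part, yld_for_patient)

    return TimeLosses(households, care_work, care_leisure, yld, patient_work)


def labour_supply(
    pop_prev: np.ndarray,
    params: HealthEconParams,
    patient_delta: np.ndarray | None = None,
    caregiver_delta: np.ndarray | None = None,
) -> np.ndarray:
    """Effective labour supplies, (H, labour type), in person-years.

    pop_prev : previous-year population (H, G, A)
    *_delta  : policy-minus-counterfactual worktime losses (H, n_illness);
               omitted deltas count as zero (the counterfactual itself).
    """
    part = np.array([params.participation[g] for g in GENDERS])
    base = np.einsum("g,hga->h", part, pop_prev[:, :, WORKING])
    loss = np.zeros_like(base)
    if patient_delta is not None:
        loss = loss + patient_delta.sum(axis=1)
    if caregiver_delta is not None:
        loss = loss + caregiver_delta.sum(axis=1)
    ls = params.skill_share * (base - loss)[:, None]
    if np.any(ls < 0):
        raise FeedbackError("negative effective labour supply")
    return ls


@dataclass
class HealthCosts:
    """Nominal excess health costs per household x non-fatal illness."""

    total: np.ndarray    # (H, 2)
    private: np.ndarray
    public: np.ndarray
    unit_costs: dict[str, np.ndarray] = field(default_factory=dict)


def health_costs(
    case_history: dict[int, np.ndarray],
    year: int,
    params: HealthEconParams,
    deflator: float,
    deflator0: float = 1.0,
) -> HealthCosts:
    """Lag-accumulated formal health costs for one year.

    ``case_history[t]`` holds (H, 2) non-fatal case totals for year ``t``;
    missing years raise (pad upstream with counterfactual levels).  Unit costs
    scale with the GDP deflator relative to its base value.
    """
    missing = [year - lag for lag in range(N_LAGS) if year - lag not in case_history]
    if missing:
        raise FeedbackError(f"case history missing for years {missing}")
    scale = deflator / deflator0
    huc = {i: scale * params.huc0[i] for i in NONFATAL}
    total = np.zeros_like(np.asarray(case_history[year], dtype=float))
    for lag in range(N_LAGS):
        cases = np.asarray(case_history[year - lag], dtype=float)
        rate = np.array([huc[i][lag] for i in NONFATAL])
        total = total + rate * cases
    public = params.public_share * total
    return HealthCosts(total=total, private=total - public, public=public, unit_costs=huc)
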