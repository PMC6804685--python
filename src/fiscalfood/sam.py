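"""Social accounting matrix: data model, CSV serialization, balancing, aggregation.

A social accounting matrix (SAM) is a square, labelled matrix of inter-account
payment flows for one base year: the cell ``flows[i, j]`` is the payment made
*by* account ``j`` (column) *to* account ``i`` (row).  Every account's receipts
(row sum) must equal its outlays (column sum).

Account labels carry a class prefix that determines their role:

========  =====================================
prefix    account class
========  =====================================
``act.``  activity (producing sector)
``com.``  commodity (marketed good/service)
``fac.``  production factor
``hh.``   representative household
``gov``   government (single account)
``s-i``   savings-investment (single account)
``row``   rest of world (single account)
========  =====================================
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Relative tolerance (fraction of the grand total) for the balance invariant.
BALANCE_RTOL = 1e-6


class AccountKind(str, enum.Enum):
    ACTIVITY = "act"
    COMMODITY = "com"
    FACTOR = "fac"
    HOUSEHOLD = "hh"
    GOVERNMENT = "gov"
    SAVINV = "s-i"
    ROW = "row"


_SINGLETONS = {"gov": AccountKind.GOVERNMENT, "s-i": AccountKind.SAVINV, "row": AccountKind.ROW}
_PREFIXES = {
    "act": AccountKind.ACTIVITY,
    "com": AccountKind.COMMODITY,
    "fac": AccountKind.FACTOR,
    "hh": AccountKind.HOUSEHOLD,
}


class SamError(ValueError):
    """Raised for structural problems with a SAM (shape, labels, balance)."""


def parse_kind(label: str) -> AccountKind:
    """Classify an account label by its prefix.

    >>> parse_kind("com.rice")
    <AccountKind.COMMODITY: 'com'>
    """
    if label in _SINGLETONS:
        return _SINGLETONS[label]
    prefix = label.split(".", 1)[0]
    if "." in label and prefix in _PREFIXES:
        return _PREFIXES[prefix]
    raise SamError(f"unknown account class for label {label!r}")


@dataclass
class SocialAccountingMatrix:
    """Balanced inter-account flow matrix.  ``flows[i, j]``: column j pays row i."""

    labels: list[str]
    flows: np.ndarray
    _kinds: list[AccountKind] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.flows = np.asarray(self.flows, dtype=float)
        if self.flows.ndim != 2 or self.flows.shape[0] != self.flows.shape[1]:
            raise SamError(f"flow matrix must be square, got shape {self.flows.shape}")
        if len(self.labels) != self.flows.shape[0]:
            raise SamError("label count does not match matrix dimension")
        if len(set(self.labels)) != len(self.labels):
            raise SamError("duplicate account labels")
        if np.any(self.flows < 0):
            bad = np.argwhere(self.flows < 0)[0]
            raise SamError(
                f"negative flow at ({self.labels[bad[0]]}, {self.labels[bad[1]]})"
            )
        self._kinds = [parse_kind(lab) for lab in self.labels]

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def kinds(self) -> list[AccountKind]:
        return list(self._kinds)

    def of_kind(self, kind: AccountKind) -> list[str]:
        return [lab for lab, k in zip(self.labels, self._kinds) if k is kind]

    @property
    def grand_total(self) -> float:
        return float(self.flows.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.flows.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.flows.sum(axis=0)

    @property
    def balance_gap(self) -> float:
        """Largest absolute row-sum/column-sum discrepancy."""
        return float(np.max(np.abs(self.row_sums - self.col_sums))) if self.n else 0.0

    def is_balanced(self, rtol: float = BALANCE_RTOL) -> bool:
        return self.balance_gap <= rtol * max(self.grand_total, 1e-300)

    def require_balanced(self, rtol: float = BALANCE_RTOL) -> None:
        if not self.is_balanced(rtol):
            raise SamError(
                f"SAM unbalanced: max |rowsum-colsum| = {self.balance_gap:.6g} "
                f"exceeds {rtol:g} x grand total ({self.grand_total:.6g})"
            )

    # -- views -------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flows, index=self.labels, columns=self.labels)

    def block(self, row_kind: AccountKind, col_kind: AccountKind) -> pd.DataFrame:
        """Sub-matrix of payments from ``col_kind`` accounts to ``row_kind`` accounts."""
        rows = self.of_kind(row_kind)
        cols = self.of_kind(col_kind)
        return self.to_frame().loc[rows, cols]

    def cell(self, row: str, col: str) -> float:
        return float(self.flows[self.labels.index(row), self.labels.index(col)])

    def copy(self) -> "SocialAccountingMatrix":
        return SocialAccountingMatrix(list(self.labels), self.flows.copy())

    # -- serialization -----------------------------------------------------

    def write_csv(self, path) -> None:
        """Write the documented CSV dialect (labelled square matrix).

        Floats are written with ``repr`` semantics so a write/read round trip
        is bit-identical.
        """
        self.to_frame().to_csv(path)


def read_sam(path, repair: bool = False, rtol: float = BALANCE_RTOL) -> SocialAccountingMatrix:
    """Read a SAM from the labelled-CSV dialect.

    Parameters
    ----------
    path : str or Path
        CSV file whose first row and column carry prefixed account labels.
    repair : bool
        If the matrix is unbalanced beyond ``rtol``, repair it with RAS
        instead of raising.
    """
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    labels = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != labels:
        raise SamError("row labels do not match column labels (matrix must be square)")
    sam = SocialAccountingMatrix(labels, frame.to_numpy(dtype=float))
    if not sam.is_balanced(rtol):
        if not repair:
            sam.require_balanced(rtol)
        sam = ras_balance(sam)
    return sam


# ---------------------------------------------------------------------------
# RAS biproportional balancing
# ---------------------------------------------------------------------------


class RasError(RuntimeError):
    """RAS failed to converge (structurally unbalanceable margins)."""


def ras(
    matrix: np.ndarray,
    row_targets: np.ndarray,
    col_targets: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, list[float]]:
    """Biproportional (RAS) scaling of ``matrix`` to target margins.

    Alternates row and column scaling; zero cells remain zero.  ``tol`` is the
    maximum relative margin error accepted.  Returns the scaled matrix and the
    per-iteration error log.

    Raises
    ------
    RasError
        If a positive target faces an all-zero row/column, or the iteration
        fails to converge within ``max_iter`` sweeps.
    """
    a = np.asarray(matrix, dtype=float).copy()
    r = np.asarray(row_targets, dtype=float)
    c = np.asarray(col_targets, dtype=float)
    if a.sum() <= 0:
        raise RasError("matrix grand total must be strictly positive")
    if abs(r.sum() - c.sum()) > tol * max(r.sum(), 1.0):
        raise RasError("row and column targets have different totals")
    if np.any((a.sum(axis=1) == 0) & (r > 0)) or np.any((a.sum(axis=0) == 0) & (c > 0)):
        raise RasError("zero row/column with positive target margin: infeasible")
    scale = max(float(np.max(np.abs(r))), 1e-300)
    log: list[float] = []
    for _ in range(max_iter):
        rs = a.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a *= np.where(rs > 0, r / np.where(rs > 0, rs, 1.0), 0.0)[:, None]
        cs = a.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            a *= np.where(cs > 0, c / np.where(cs > 0, cs, 1.0), 0.0)[None, :]
        err = max(
            float(np.max(np.abs(a.sum(axis=1) - r))),
            float(np.max(np.abs(a.sum(axis=0) - c))),
        ) / scale
        log.append(err)
        if err <= tol:
            return a, log
    raise RasError(f"RAS did not converge in {max_iter} iterations (err={log[-1]:.3g})")


def ras_balance(
    sam: SocialAccountingMatrix, tol: float = 1e-9, max_iter: int = 10_000
) -> SocialAccountingMatrix:
    """Balance a SAM with RAS toward the average of its row/column margins.

    An already-balanced SAM (within ``tol`` relative to the margin scale) is
    returned unchanged.
    """
    if sam.grand_total <= 0:
        raise RasError("SAM grand total must be strictly positive")
    targets = 0.5 * (sam.row_sums + sam.col_sums)
    scale = max(float(np.max(targets)), 1e-300)
    if sam.balance_gap <= tol * scale:
        return sam
    balanced, log = ras(sam.flows, targets, targets, tol=tol, max_iter=max_iter)
    logger.info("RAS balance: %d iterations, final error %.3g", len(log), log[-1])
    return SocialAccountingMatrix(list(sam.labels), balanced)


# ---------------------------------------------------------------------------
# Sector aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectorMap:
    """Total mapping from fine commodity/activity sector names to coarse groups.

    Sector names are bare (without the ``act.``/``com.`` prefix); the same map
    applies to both activities and commodities.  ``food`` flags the coarse
    groups that count as food sectors.
    """

    fine: tuple[str, ...]
    coarse: tuple[str, ...]
    mapping: dict[str, str]
    food: frozenset[str]

    def __post_init__(self) -> None:
        missing = [s for s in self.fine if s not in self.mapping]
        if missing:
            raise ValueError(f"sectors without a coarse group: {missing}")
        bad = [s for s, g in self.mapping.items() if g not in self.coarse]
        if bad:
            raise ValueError(f"sectors mapped to unknown coarse group: {bad}")
        unknown_food = self.food - set(self.coarse)
        if unknown_food:
            raise ValueError(f"food flags for unknown coarse sectors: {sorted(unknown_food)}")

    @classmethod
    def identity(cls, sectors: list[str], food: set[str] | None = None) -> "SectorMap":
        return cls(
            fine=tuple(sectors),
            coarse=tuple(sectors),
            mapping={s: s for s in sectors},
            food=frozenset(food or ()),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fine": list(self.fine),
                "coarse": [self.mapping[s] for s in self.fine],
                "food": [self.mapping[s] in self.food for s in self.fine],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SectorMap":
        coarse_order = list(dict.fromkeys(frame["coarse"]))
        food = {
            row.coarse for row in frame.itertuples() if bool(row.food)
        }
        return cls(
            fine=tuple(frame["fine"]),
            coarse=tuple(coarse_order),
            mapping=dict(zip(frame["fine"], frame["coarse"])),
            food=frozenset(food),
        )


def aggregate(sam: SocialAccountingMatrix, smap: SectorMap) -> SocialAccountingMatrix:
    """Sum activity/commodity flows into coarse groups; balance is preserved exactly.

    Non-sector accounts (factors, households, government, s-i, row) pass
    through unchanged, keeping their order after the aggregated sectors.
    """
    new_labels: list[str] = []
    groups: dict[str, list[int]] = {}
    for idx, (lab, kind) in enumerate(zip(sam.labels, sam.kinds)):
        if kind in (AccountKind.ACTIVITY, AccountKind.COMMODITY):
            name = lab.split(".", 1)[1]
            if name not in smap.mapping:
                raise SamError(f"sector {name!r} missing from the sector map")
            new_lab = f"{kind.value}.{smap.mapping[name]}"
        else:
            new_lab = lab
        if new_lab not in groups:
            groups[new_lab] = []
            new_labels.append(new_lab)
        groups[new_lab].append(idx)

    agg = np.zeros((len(new_labels), len(new_labels)))
    for i, lab_i in enumerate(new_labels):
        rows = groups[lab_i]
        for j, lab_j in enumerate(new_labels):
            cols = groups[lab_j]
            agg[i, j] = sam.flows[np.ix_(rows, cols)].sum()
    return SocialAccountingMatrix(new_labels, agg)
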