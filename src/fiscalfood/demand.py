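"""Almost Ideal Demand System: calibration from elasticities, and evaluation.

Each household's expenditure shares are linear in log prices and the log of
expenditure deflated by an economy-wide price index P (here the GDP deflator):

    w_c = alpha_c + beta_c * log(e / P) + sum_c' gamma_{c,c'} * log(p_c')

Because P is an economy-wide deflator (not a function of the household's own
prices), the share-elasticity relations at the base point are

    eta_c            = 1 + beta_c / w_c                      (income)
    eps_{c,c'}       = -1[c=c'] + gamma_{c,c'} / w_c          (uncompensated price)

Calibration inverts these and then projects (beta, gamma) onto the exact
adding-up / homogeneity / symmetry constraint set by least squares, logging the
projection distance, since literature elasticities are generally inconsistent
with the exact restrictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class DemandError(ValueError):
    pass


@dataclass
class DemandSystem:
    """Calibrated AIDS parameters for one household."""

    commodities: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    base_shares: np.ndarray
    base_expenditure: float
    base_prices: np.ndarray
    base_deflator: float = 1.0
    #: L2 distance moved by the consistency projection during calibration.
    projection_distance: float = 0.0
    clip_warnings: int = field(default=0, repr=False)

    @property
    def n(self) -> int:
        return len(self.commodities)

    def shares(self, prices: np.ndarray, expenditure: float, deflator: float) -> np.ndarray:
        """Expenditure shares at the given point (clipped to be non-negative).

        Shares below -0.01 indicate an evaluation far outside the regular
        region and are logged before clipping.
        """
        prices = np.asarray(prices, dtype=float)
        if np.any(prices <= 0) or expenditure <= 0 or deflator <= 0:
            raise DemandError("prices, expenditure and deflator must be positive")
        w = (
            self.alpha
            + self.beta * np.log(expenditure / deflator)
            + self.gamma @ np.log(prices)
        )
        if np.any(w < -0.01):
            self.clip_warnings += 1
            logger.warning(
                "AIDS share %.4f below -0.01: evaluation outside regular region", w.min()
            )
        if np.any(w < 0):
            w = np.maximum(w, 0.0)
            w = w / w.sum()
        return w

    def __call__(self, prices, expenditure, deflator):
        return demand(self, prices, expenditure, deflator)


def demand(
    ds: DemandSystem, prices: np.ndarray, expenditure: float, deflator: float
) -> np.ndarray:
    """Commodity quantities ``x_c = w_c * e / p_c``."""
    prices = np.asarray(prices, dtype=float)
    w = ds.shares(prices, expenditure, deflator)
    return w * expenditure / prices


def calibrate_aids(
    base_shares: np.ndarray,
    income_elasticities: np.ndarray,
    price_elasticities: np.ndarray,
    commodities: list[str] | None = None,
    base_expenditure: float = 1.0,
    base_prices: np.ndarray | None = None,
    base_deflator: float = 1.0,
) -> DemandSystem:
    """Calibrate AIDS parameters to base shares and elasticities.

    The supplied elasticities are matched exactly at the base point *before*
    projection onto the adding-up/homogeneity/symmetry constraint set; the
    projection distance is stored on the returned system and logged.

    Raises
    ------
    DemandError
        If base shares do not sum to one, or a commodity has zero base share
        but a non-zero elasticity.
    """
    w0 = np.asarray(base_shares, dtype=float)
    eta = np.asarray(income_elasticities, dtype=float)
    eps = np.asarray(price_elasticities, dtype=float)
    n = w0.size
    if commodities is None:
        commodities = [f"c{i}" for i in range(n)]
    if abs(w0.sum() - 1.0) > 1e-8:
        raise DemandError(f"base shares must sum to 1, got {w0.sum():.8f}")
    if np.any(w0 < 0):
        raise DemandError("base shares must be non-negative")
    zero = w0 == 0
    if np.any(zero & (eta != 0)) or np.any(zero & (np.abs(eps).sum(axis=1) > 0)):
        raise DemandError("zero base share with non-zero elasticity is not calibrable")
    if eps.shape != (n, n):
        raise DemandError("price elasticity matrix not conformable with shares")

    beta = w0 * (eta - 1.0)
    gamma = w0[:, None] * (eps + np.eye(n))

    # Least-squares projection onto the exact AIDS restrictions:
    # symmetry, homogeneity (rows of gamma sum to 0), adding-up (columns of
    # gamma sum to 0, beta sums to 0).
    gamma_sym = 0.5 * (gamma + gamma.T)
    centering = np.eye(n) - np.ones((n, n)) / n
    gamma_proj = centering @ gamma_sym @ centering
    beta_proj = beta - beta.mean()
    distance = float(
        np.sqrt(np.sum((gamma_proj - gamma) ** 2) + np.sum((beta_proj - beta) ** 2))
    )
    if distance > 1e-12:
        logger.info("AIDS consistency projection moved parameters by %.3g (L2)", distance)

    p0 = np.ones(n) if base_prices is None else np.asarray(base_prices, dtype=float)
    alpha = (
        w0
        - beta_proj * np.log(base_expenditure / base_deflator)
        - gamma_proj @ np.log(p0)
    )
    return DemandSystem(
        commodities=list(commodities),
        alpha=alpha,
        beta=beta_proj,
        gamma=gamma_proj,
        base_shares=w0,
        base_expenditure=float(base_expenditure),
        base_prices=p0,
        base_deflator=float(base_deflator),
        projection_distance=distance,
    )


def implied_elasticities(ds: DemandSystem) -> tuple[np.ndarray, np.ndarray]:
    """Income and uncompensated price elasticities of the calibrated system
    at its base point (deflator held fixed)."""
    w0 = ds.base_shares
    eta = 1.0 + ds.beta / w0
    eps = -np.eye(ds.n) + ds.gamma / w0[:, None]
    return eta, eps
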