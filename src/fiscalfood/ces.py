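"""CES aggregation and CET transformation nests with benchmark calibration.

Conventions: a CES nest ``Y = alpha * (sum_i delta_i X_i^(-rho))^(-1/rho)`` with
substitution elasticity ``sigma = 1/(1+rho)``; a CET nest
``Y = alpha * (sum_i delta_i X_i^rho)^(1/rho)`` with transformation elasticity
``sigma = 1/(rho-1)``.  Calibration picks (alpha, delta) so that base prices,
base quantities and the base aggregate value are an exact cost-minimizing
(revenue-maximizing) point, with the base dual price equal to 1 when the
aggregate quantity unit is the base value.  The Cobb-Douglas limit sigma=1 is
supported for CES nests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CesNest:
    """Constant-elasticity input aggregator calibrated to a benchmark point."""

    delta: np.ndarray
    alpha: float
    sigma: float

    @classmethod
    def calibrate(cls, x0: np.ndarray, p0: np.ndarray, sigma: float) -> "CesNest":
        """Calibrate to base input quantities/prices; aggregate unit = base value."""
        x0 = np.asarray(x0, dtype=float)
        p0 = np.asarray(p0, dtype=float)
        if np.any(x0 <= 0) or np.any(p0 <= 0):
            raise ValueError("CES calibration requires strictly positive base data")
        y0 = float(p0 @ x0)
        if sigma == 1.0:
            delta = p0 * x0 / y0
            alpha = y0 / np.prod(x0**delta)
            return cls(delta=delta, alpha=float(alpha), sigma=1.0)
        rho = (1.0 - sigma) / sigma
        raw = p0 * x0 ** (1.0 + rho)
        delta = raw / raw.sum()
        alpha = y0 / (delta @ x0 ** (-rho)) ** (-1.0 / rho)
        return cls(delta=delta, alpha=float(alpha), sigma=sigma)

    def quantity(self, x: np.ndarray, shift: float = 1.0) -> float:
        x = np.asarray(x, dtype=float)
        a = self.alpha * shift
        if self.sigma == 1.0:
            return float(a * np.prod(x**self.delta))
        rho = (1.0 - self.sigma) / self.sigma
        return float(a * (self.delta @ x ** (-rho)) ** (-1.0 / rho))

    def dual_price(self, p: np.ndarray, shift: float = 1.0) -> float:
        """Unit cost of the aggregate at input prices ``p``."""
        p = np.asarray(p, dtype=float)
        a = self.alpha * shift
        if self.sigma == 1.0:
            return float(np.prod((p / self.delta) ** self.delta) / a)
        s = self.sigma
        return float((self.delta**s @ p ** (1.0 - s)) ** (1.0 / (1.0 - s)) / a)

    def demands(self, y: float, p: np.ndarray, shift: float = 1.0) -> np.ndarray:
        """Cost-minimizing input quantities for aggregate output ``y``."""
        p = np.asarray(p, dtype=float)
        a = self.alpha * shift
        c = self.dual_price(p, shift)
        if self.sigma == 1.0:
            return self.delta * c * y / p
        return (y / a) * (self.delta * a * c / p) ** self.sigma


@dataclass
class CetNest:
    """Constant-elasticity output transformation calibrated to a benchmark point."""

    delta: np.ndarray
    alpha: float
    sigma: float

    @classmethod
    def calibrate(cls, x0: np.ndarray, p0: np.ndarray, sigma: float) -> "CetNest":
        x0 = np.asarray(x0, dtype=float)
        p0 = np.asarray(p0, dtype=float)
        if np.any(x0 <= 0) or np.any(p0 <= 0):
            raise ValueError("CET calibration requires strictly positive base data")
        if sigma <= 0:
            raise ValueError("CET elasticity must be positive")
        y0 = float(p0 @ x0)
        rho = 1.0 + 1.0 / sigma
        raw = p0 * x0 ** (1.0 - rho)
        delta = raw / raw.sum()
        alpha = y0 / (delta @ x0**rho) ** (1.0 / rho)
        return cls(delta=delta, alpha=float(alpha), sigma=sigma)

    def dual_price(self, p: np.ndarray) -> float:
        """Unit revenue of the aggregate at output prices ``p``."""
        p = np.asarray(p, dtype=float)
        s = self.sigma
        return float((self.delta ** (-s) @ p ** (1.0 + s)) ** (1.0 / (1.0 + s)) / self.alpha)

    def supplies(self, y: float, p: np.ndarray) -> np.ndarray:
        """Revenue-maximizing output quantities for aggregate input ``y``."""
        p = np.asarray(p, dtype=float)
        r = self.dual_price(p)
        return (y / self.alpha) * (p / (self.delta * self.alpha * r)) ** self.sigma
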