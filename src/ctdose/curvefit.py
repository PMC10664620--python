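"""Least-squares power-curve fitting, sklearn-style.

Fits ``y = beta * (x - x_min) ** nu`` by non-linear least squares over
``beta > 0, nu > 0``.  Power fits have a shallow valley in ``nu``, so the
optimiser is multi-started over a spread of exponents and the best local
minimum is kept.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["PowerCurveRegressor", "fit_power_curve"]


class PowerCurveRegressor(RegressorMixin, BaseEstimator):
    """Non-linear least squares for ``y = beta * (x - x_min) ** nu``.

    Parameters
    ----------
    x_min : float
        Dose offset; doses at ``x_min`` have zero expected response.
    starts : sequence of float
        Initial exponents for the multi-start search.

    Attributes
    ----------
    beta_, nu_ : float
        Least-squares estimates.
    cost_ : float
        Residual sum of squares at the optimum.
    """

    def __init__(self, x_min: float = 0.0, starts: Sequence[float] = (0.25, 0.5, 1.0, 2.0)):
        self.x_min = x_min
        self.starts = starts

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("X and y must have equal length")
        if np.unique(x).size < 2:
            raise ValueError("need at least two distinct doses")
        xs = x - self.x_min
        if np.any(xs < 0):
            raise ValueError("all doses must be >= x_min")

        def residuals(p):
            return y - p[0] * xs ** p[1]

        best = None
        for nu0 in self.starts:
            w = xs**nu0
            denom = float(w @ w)
            beta0 = max(float(w @ y) / denom, 1e-8) if denom > 0 else 1.0
            sol = least_squares(
                residuals,
                x0=[beta0, nu0],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("power-curve fit did not converge from any start")
        self.beta_ = float(best.x[0])
        self.nu_ = float(best.x[1])
        self.cost_ = float(2.0 * best.cost)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.beta_ * (x - self.x_min) ** self.nu_


def fit_power_curve(doses, responses, x_min: float) -> tuple[float, float]:
    """Thin wrapper: least-squares ``(beta_hat, nu_hat)`` of the power curve."""
    reg = PowerCurveRegressor(x_min=x_min).fit(doses, responses)
    return reg.beta_, reg.nu_
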