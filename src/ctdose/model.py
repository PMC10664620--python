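"""Densities and closed-form MTD of the three-parameter power-curve model.

The toxicity response at dose ``x`` is modelled as

    y | beta, nu, sigma ~ Normal(beta * (x - x_min) ** nu, sigma ** 2)

with positive slope ``beta``, exponent ``nu`` and noise scale ``sigma``.
Under the constraints ``0 < sigma < eta / Phi^{-1}(gamma)`` and
``beta > l(sigma, nu)`` the maximum tolerated dose — the largest dose at
which a response stays below ``eta`` with probability at least ``gamma`` —
has the closed form

    xi = x_min + ((eta - sigma * Phi^{-1}(gamma)) / beta) ** (1 / nu)

and lies inside the dose range.  The joint prior is chosen so that every
draw respects these constraints: ``beta | nu, sigma`` is uniform on
``(l(sigma, nu), u(sigma, nu))``, ``sigma`` follows a unit half-Cauchy
truncated to ``(0, eta / Phi^{-1}(gamma))``, and ``nu`` is log-normal with
unit median and scale ``delta``.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Tuple, Union

import numpy as np
from scipy.special import ndtr

from .config import DesignConfig, ModelParams

if TYPE_CHECKING:  # pragma: no cover
    from .dose_rule import TrialData

__all__ = [
    "prior_bounds",
    "mtd",
    "mtd_from_params",
    "log_prior",
    "log_likelihood",
    "sample_prior",
    "dlt_probability",
]

ArrayLike = Union[float, np.ndarray]


def prior_bounds(sigma: ArrayLike, nu: ArrayLike, config: DesignConfig) -> Tuple[ArrayLike, ArrayLike]:
    """Support ``(l, u)`` of the conditional uniform prior for the slope.

    ``l(sigma, nu) = (eta - sigma * Phi^{-1}(gamma)) / (x_max - x_min) ** nu``
    is the smallest slope keeping the MTD below ``x_max``;
    ``u(sigma, nu) = eta / (x_max - x_min) ** nu + sigma * Phi^{-1}(gamma)``
    merely makes the conditional uniform proper.  Always ``0 < l < u``.
    """
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(sigma <= 0) or np.any(sigma >= config.sigma_max):
        raise ValueError(
            f"sigma must lie in (0, {config.sigma_max:.6g}) for gamma={config.gamma}"
        )
    if np.any(nu <= 0):
        raise ValueError("nu must be positive")
    span_nu = config.dose_span**nu
    lower = (config.eta - sigma * config.z_gamma) / span_nu
    upper = config.eta / span_nu + sigma * config.z_gamma
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper


def mtd(beta: ArrayLike, nu: ArrayLike, sigma: ArrayLike, config: DesignConfig) -> ArrayLike:
    """Closed-form MTD ``xi = x_min + ((eta - sigma*z_gamma)/beta)**(1/nu)``.

    Vectorised over parameter arrays (used to map posterior draws to MTD
    draws).  Raises when the MTD is undefined: non-positive slope or
    exponent, or ``sigma >= eta / Phi^{-1}(gamma)`` (the safety margin
    ``eta - sigma * Phi^{-1}(gamma)`` would be non-positive).
    """
    beta = np.asarray(beta, dtype=float)
    nu = np.asarray(nu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(beta <= 0) or np.any(nu <= 0):
        raise ValueError("beta and nu must be positive")
    margin = config.eta - sigma * config.z_gamma
    if np.any(margin <= 0):
        raise ValueError(
            f"MTD undefined: sigma >= eta/Phi^-1(gamma) = {config.sigma_max:.6g}"
        )
    out = config.x_min + (margin / beta) ** (1.0 / nu)
    return float(out) if out.ndim == 0 else out


def mtd_from_params(params: ModelParams, config: DesignConfig) -> float:
    """MTD of a parameter triple; in ``(x_min, x_max)`` whenever ``beta > l``."""
    return float(mtd(params.beta, params.nu, params.sigma, config))


def log_prior(params: ModelParams, config: DesignConfig) -> float:
    """Joint log prior density of ``(beta, nu, sigma)``; ``-inf`` off-support.

    Normalising constants are included, so ``exp(log_prior)`` integrates to
    one over the support.  Out-of-support parameters yield ``-inf`` rather
    than an exception so samplers can reject gracefully.
    """
    beta, nu, sigma = params.beta, params.nu, params.sigma
    if not (0.0 < sigma < config.sigma_max) or nu <= 0.0:
        return -math.inf
    lower, upper = prior_bounds(sigma, nu, config)
    if not lower < beta < upper:
        return -math.inf
    lp = -math.log(upper - lower)
    # half-Cauchy(0, 1) truncated to (0, sigma_max): 1 / (atan(sigma_max) (1 + s^2))
    lp += -math.log(math.atan(config.sigma_max)) - math.log1p(sigma * sigma)
    # log-normal(0, delta^2) for nu
    lp += (
        -math.log(nu * config.delta * math.sqrt(2.0 * math.pi))
        - (math.log(nu) ** 2) / (2.0 * config.delta**2)
    )
    return lp


def log_likelihood(params: ModelParams, data: "TrialData | None", config: DesignConfig) -> float:
    """Gaussian log likelihood of accrued (dose, response) records.

    An empty information set contributes zero, so the posterior equals the
    prior before any patient is observed.
    """
    if data is None or len(data) == 0:
        return 0.0
    x = np.asarray(data.doses, dtype=float)
    y = np.asarray(data.responses, dtype=float)
    if np.any(x < config.x_min):
        raise ValueError("invalid dose: every dose must satisfy x >= x_min")
    mean = params.beta * (x - config.x_min) ** params.nu
    resid = y - mean
    n = x.size
    return float(
        -0.5 * n * math.log(2.0 * math.pi)
        - n * math.log(params.sigma)
        - float(resid @ resid) / (2.0 * params.sigma**2)
    )


def dlt_probability(x: ArrayLike, params: ModelParams, config: DesignConfig) -> ArrayLike:
    """``Pr[Y(x) >= eta]`` under the model; non-decreasing in the dose."""
    x = np.asarray(x, dtype=float)
    mean = params.beta * (x - config.x_min) ** params.nu
    out = ndtr((mean - config.eta) / params.sigma)
    return float(out) if out.ndim == 0 else out


def sample_prior(config: DesignConfig, n: int, rng: np.random.Generator | None = None):
    """Exact joint prior draws of ``(beta, nu, sigma)`` as arrays.

    sigma by inverse-CDF of the truncated half-Cauchy, nu by exponentiating
    a normal, beta uniform on its conditional support.
    """
    rng = np.random.default_rng() if rng is None else rng
    u = rng.random(n)
    sigma = np.tan(u * math.atan(config.sigma_max))
    nu = np.exp(rng.normal(0.0, config.delta, size=n))
    lower, upper = prior_bounds(sigma, nu, config)
    beta = lower + rng.random(n) * (upper - lower)
    return beta, nu, sigma
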