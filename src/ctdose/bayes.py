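"""Posterior sampling for the three-parameter model, sklearn-style.

``BayesianToxicityModel`` is the fit-shaped surface: ``fit(X, y)`` draws from
the joint posterior of ``(beta, nu, sigma)`` given accrued (dose, response)
pairs and exposes the draws — and the derived MTD draws — as fitted
attributes.  ``sample_posterior`` and ``posterior_mtd_quantile`` are thin
functional wrappers used by the dose-finding rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import model as _model
from ._kernel import run_chain
from .config import DesignConfig, ModelParams, SamplerSettings

__all__ = [
    "PosteriorDraws",
    "BayesianToxicityModel",
    "sample_posterior",
    "posterior_mtd_quantile",
]


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint draws of the model parameters and the derived MTD draws.

    ``xi`` is the Monte-Carlo representation of the posterior distribution
    of the MTD; its empirical quantiles drive the dose-finding rule.
    """

    beta: np.ndarray
    nu: np.ndarray
    sigma: np.ndarray
    xi: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.beta.size

    def mtd_quantile(self, alpha: float) -> float:
        """Lower (inverted-CDF) empirical ``alpha``-quantile of the MTD draws.

        The type-1 convention never exceeds the interpolated quantile, which
        is the conservative choice for overdose control.
        """
        return posterior_mtd_quantile(self, alpha)


def _default_init(config: DesignConfig) -> ModelParams:
    """Always-in-support start: sigma at half its bound, nu = 1, beta central."""
    sigma0 = 0.5 * config.sigma_max
    lower, upper = _model.prior_bounds(sigma0, 1.0, config)
    return ModelParams(0.5 * (lower + upper), 1.0, sigma0)


def sample_posterior(
    data,
    config: DesignConfig,
    settings: SamplerSettings | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior given accrued trial data.

    With no data the posterior equals the prior; the chain then simply
    explores the constrained prior.  Deterministic given ``settings.seed``.
    """
    settings = SamplerSettings() if settings is None else settings
    if data is None or len(data) == 0:
        x = np.empty(0)
        y = np.empty(0)
    else:
        x = np.asarray(data.doses, dtype=float)
        y = np.asarray(data.responses, dtype=float)
        if np.any(x < config.x_min) or np.any(x >= config.x_max):
            raise ValueError("doses must lie in [x_min, x_max)")
    init = settings.init if settings.init is not None else _default_init(config)
    out = run_chain(
        x,
        y,
        config.x_min,
        config.dose_span,
        config.eta,
        config.z_gamma,
        config.sigma_max,
        config.delta,
        settings.n_iterations,
        settings.n_burnin,
        settings.thin,
        int(settings.seed) % 2**31,
        init.beta,
        init.nu,
        init.sigma,
    )
    beta, nu, sigma = out[:, 0], out[:, 1], out[:, 2]
    if x.size > 0 and (np.ptp(beta) == 0.0 or np.ptp(sigma) == 0.0):
        warnings.warn(
            "posterior chain did not move; draws may not represent the posterior",
            RuntimeWarning,
        )
    xi = _model.mtd(beta, nu, sigma, config)
    return PosteriorDraws(beta=beta, nu=nu, sigma=sigma, xi=xi)


def posterior_mtd_quantile(draws: PosteriorDraws, alpha: float) -> float:
    """Empirical ``alpha``-quantile of the MTD draws (inverted-CDF rule)."""
    if draws.n_draws < 1:
        raise ValueError("empty draws")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(np.quantile(draws.xi, alpha, method="inverted_cdf"))


class BayesianToxicityModel(BaseEstimator):
    """Bayesian power-curve toxicity regression with MTD-preserving priors.

    Parameters
    ----------
    config : DesignConfig
        Design constants (dose range, eta, gamma, delta, ...) that define the
        MTD and pin down the constrained prior.
    n_iterations, n_burnin, thin : int
        MCMC schedule of the slice-within-Gibbs sampler.
    random_state : int
        Seed of the chain; runs are bit-reproducible.

    Attributes
    ----------
    draws_ : PosteriorDraws
        Joint posterior draws of ``(beta, nu, sigma)`` and the MTD.
    mtd_draws_ : ndarray
        Alias of ``draws_.xi``.
    n_obs_ : int
        Number of (dose, response) pairs seen by ``fit``.
    """

    def __init__(
        self,
        config: DesignConfig,
        n_iterations: int = 4000,
        n_burnin: int = 1000,
        thin: int = 1,
        random_state: int = 0,
    ):
        self.config = config
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y=None):
        """Sample the posterior given doses ``X`` (shape (n,) or (n, 1))."""
        x = np.asarray(X, dtype=float).reshape(-1)
        if y is None:
            if x.size:
                raise ValueError("responses y are required when doses are given")
            y = np.empty(0)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ValueError("doses and responses must have equal length")

        from .dose_rule import TrialData  # local import to avoid a cycle

        data = TrialData.from_arrays(x, y) if x.size else None
        settings = SamplerSettings(
            n_iterations=self.n_iterations,
            n_burnin=self.n_burnin,
            thin=self.thin,
            seed=self.random_state,
        )
        self.draws_ = sample_posterior(data, self.config, settings)
        self.mtd_draws_ = self.draws_.xi
        self.n_obs_ = int(x.size)
        return self

    def predict(self, X):
        """Posterior-mean toxicity response at the given doses."""
        self._check_fitted()
        x = np.asarray(X, dtype=float).reshape(-1)
        xs = x[:, None] - self.config.x_min
        mean = self.draws_.beta[None, :] * xs ** self.draws_.nu[None, :]
        return mean.mean(axis=1)

    def mtd_quantile(self, alpha: Optional[float] = None) -> float:
        """Posterior quantile of the MTD; defaults to the feasibility bound."""
        self._check_fitted()
        alpha = self.config.alpha if alpha is None else alpha
        return posterior_mtd_quantile(self.draws_, alpha)

    def _check_fitted(self) -> None:
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted; call fit(X, y) first")
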