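"""Design constants and parameter containers for continuous-toxicity dose finding.

A phase I design is specified by the clinician-set constants that define the
maximum tolerated dose (MTD) and the trial logistics:

* ``eta`` -- maximum toxicity level: a response ``y >= eta`` is a
  dose-limiting toxicity (DLT).
* ``gamma`` -- homogeneity constant in (0.5, 1); ``theta = 1 - gamma`` is the
  target toxicity level, the acceptable DLT probability at the MTD.
* ``(x_min, x_max)`` -- admissible dose range; the MTD is assumed to lie
  inside it.
* ``alpha`` -- feasibility bound: the next dose is the posterior
  ``alpha``-quantile of the MTD, so the posterior probability of overdosing
  any patient is bounded by ``alpha``.
* ``delta`` -- prior scale of the non-linearity exponent ``nu``
  (log-normal with unit median).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from scipy.special import ndtri

__all__ = ["DesignConfig", "ModelParams", "TruthSpec", "SamplerSettings"]


@dataclass
class DesignConfig:
    """Clinician-set constants defining the MTD, the DLT, and the trial."""

    eta: float
    gamma: float
    x_min: float
    x_max: float
    delta: float
    alpha: float
    initial_dose: float
    n_patients: int
    cohort_size: int = 1
    dose_grid: Optional[Sequence[float]] = None
    grid_snap: str = "nearest"
    monotone: bool = False
    max_increment: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if not 0.5 < self.gamma < 1:
            raise ValueError(f"gamma must lie in (0.5, 1), got {self.gamma}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.x_min < self.x_max:
            raise ValueError(
                f"dose range must satisfy 0 < x_min < x_max, got ({self.x_min}, {self.x_max})"
            )
        if not self.x_min < self.initial_dose < self.x_max:
            raise ValueError(
                f"initial_dose {self.initial_dose} outside ({self.x_min}, {self.x_max})"
            )
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be a positive integer")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be a positive integer")
        if self.max_increment is not None and not self.max_increment > 0:
            raise ValueError("max_increment must be positive when set")
        if self.grid_snap not in ("nearest", "ceiling"):
            raise ValueError("grid_snap must be 'nearest' or 'ceiling'")
        if self.dose_grid is not None:
            grid = tuple(float(d) for d in self.dose_grid)
            if len(grid) == 0:
                raise ValueError("dose_grid must be non-empty when set")
            if any(not self.x_min < d < self.x_max for d in grid):
                raise ValueError("every grid dose must lie inside (x_min, x_max)")
            if list(grid) != sorted(set(grid)):
                raise ValueError("dose_grid must be strictly increasing")
            self.dose_grid = grid

    # -- derived quantities -------------------------------------------------

    @property
    def theta(self) -> float:
        """Target toxicity level ``1 - gamma`` (never stored separately)."""
        return 1.0 - self.gamma

    @property
    def z_gamma(self) -> float:
        """Standard-normal quantile at ``gamma``."""
        return float(ndtri(self.gamma))

    @property
    def sigma_max(self) -> float:
        """Upper support limit ``eta / Phi^{-1}(gamma)`` for sigma."""
        return self.eta / self.z_gamma

    @property
    def dose_span(self) -> float:
        return self.x_max - self.x_min

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["dose_grid"] is not None:
            d["dose_grid"] = list(d["dose_grid"])
        return d


@dataclass(frozen=True)
class ModelParams:
    """A (slope, exponent, standard deviation) triple of the toxicity curve.

    The mean toxicity at dose ``x`` is ``beta * (x - x_min) ** nu`` and
    patient responses scatter around it with standard deviation ``sigma``.
    """

    beta: float
    nu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.beta > 0 and self.nu > 0 and self.sigma > 0):
            raise ValueError(
                f"beta, nu, sigma must all be positive, got "
                f"({self.beta}, {self.nu}, {self.sigma})"
            )

    def validate(self, config: DesignConfig) -> None:
        """Check the constraints that make the MTD well defined and in-range."""
        if not self.sigma < config.sigma_max:
            raise ValueError(
                f"sigma={self.sigma} must be < eta/Phi^-1(gamma)={config.sigma_max:.6g}"
            )
        lower = (config.eta - self.sigma * config.z_gamma) / config.dose_span**self.nu
        if not self.beta > lower:
            raise ValueError(
                f"beta={self.beta} must exceed the lower bound l(sigma, nu)={lower:.6g}"
            )


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for simulated trials: true MTD, exponent and noise level.

    The true slope is not free: it is pinned down by requiring the
    closed-form MTD of the triple ``(beta0, nu0, sigma0)`` to equal ``xi0``.
    """

    xi0: float
    nu0: float
    sigma0: float

    def __post_init__(self) -> None:
        if not (self.xi0 > 0 and self.nu0 > 0 and self.sigma0 >= 0):
            raise ValueError("xi0 and nu0 must be positive; sigma0 non-negative")

    def beta0(self, config: DesignConfig) -> float:
        """Slope implied by the true MTD under the design constants."""
        if not config.x_min < self.xi0 < config.x_max:
            raise ValueError(
                f"true MTD {self.xi0} outside dose range "
                f"({config.x_min}, {config.x_max})"
            )
        margin = config.eta - self.sigma0 * config.z_gamma
        if margin <= 0:
            raise ValueError("sigma0 too large: eta - sigma0 * Phi^-1(gamma) <= 0")
        return margin / (self.xi0 - config.x_min) ** self.nu0

    def params(self, config: DesignConfig) -> ModelParams:
        sigma = self.sigma0 if self.sigma0 > 0 else math.nextafter(0.0, 1.0)
        return ModelParams(self.beta0(config), self.nu0, sigma)


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run length and seeding."""

    n_iterations: int = 4000
    n_burnin: int = 1000
    thin: int = 1
    seed: int = 0
    init: Optional[ModelParams] = None

    def __post_init__(self) -> None:
        if not self.n_iterations > self.n_burnin >= 0:
            raise ValueError("require n_iterations > n_burnin >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def with_seed(self, seed: int) -> "SamplerSettings":
        return SamplerSettings(self.n_iterations, self.n_burnin, self.thin, int(seed), self.init)
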