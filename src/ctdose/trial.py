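"""Closed-loop adaptive trials: fully sequential and cohort-sequential designs.

A trial starts every patient pathway at ``config.initial_dose``.  After each
patient (cohort size 1, the fully sequential design) or each cohort of size
``C`` (the cohort-sequential design), the posterior is refreshed and the
next dose is the feasibility-bounded posterior quantile of the MTD, with
any configured options (increment cap, monotone escalation, discrete grid)
applied.  The dose assigned to the last patient/cohort is the trial's MTD
estimate.

Randomness is split into two independent seeded streams — one for simulated
patient responses, one for the MCMC chains — so changing sampler settings
never perturbs the simulated patients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Generator, Optional

import numpy as np

from .config import DesignConfig, SamplerSettings, TruthSpec
from .dose_rule import StoppingRule, TrialData, check_stopping, next_dose

__all__ = ["TrialResult", "generate_response", "run_trial", "simulate_trial", "interactive_trial"]

logger = logging.getLogger(__name__)


@dataclass
class TrialResult:
    """Outcome of one trial: assigned doses, responses, and the MTD estimate."""

    data: TrialData
    mtd_estimate: float
    config: DesignConfig
    truth: Optional[TruthSpec] = None
    stopped_early: bool = False
    decisions: list = field(default_factory=list)

    @property
    def doses(self) -> np.ndarray:
        return self.data.doses

    @property
    def responses(self) -> np.ndarray:
        return self.data.responses

    def metrics(self, n: Optional[int] = None) -> dict:
        from .diagnostics import compute_metrics

        if self.truth is None:
            raise ValueError("missing truth: metrics need a TruthSpec")
        return compute_metrics(self, self.truth, self.config, n)


def generate_response(
    dose: float,
    truth: TruthSpec,
    config: DesignConfig,
    rng: np.random.Generator,
) -> float:
    """One simulated continuous toxicity response at ``dose``.

    Gaussian around the true power curve ``beta0 * (x - x_min) ** nu0`` with
    standard deviation ``sigma0``; responses are conditionally independent
    across patients given their doses.
    """
    if not config.x_min <= dose < config.x_max:
        raise ValueError(f"invalid dose {dose}: outside [x_min, x_max)")
    mean = truth.beta0(config) * (dose - config.x_min) ** truth.nu0
    if truth.sigma0 == 0.0:
        return float(mean)
    return float(rng.normal(mean, truth.sigma0))


def _sampler_seed(base_seed: int, step: int) -> int:
    """Stable per-decision chain seed, kept below 2**31."""
    ss = np.random.SeedSequence(entropy=int(base_seed) % 2**31, spawn_key=(step,))
    return int(ss.generate_state(1)[0] % 2**31)


def run_trial(
    config: DesignConfig,
    response_source: Callable[[float], float],
    settings: Optional[SamplerSettings] = None,
    truth: Optional[TruthSpec] = None,
    stopping: Optional[StoppingRule] = None,
    decision_fn: Optional[Callable] = None,
) -> TrialResult:
    """Run one adaptive trial with a pluggable response source.

    ``response_source(dose)`` supplies each patient's continuous response —
    a truth-driven simulator, a recorded dataset, or a live provider.
    ``decision_fn(data, config, settings)`` may replace the posterior-quantile
    rule (used for stubbing in tests and for custom rules).
    """
    settings = SamplerSettings() if settings is None else settings
    decide = decision_fn if decision_fn is not None else next_dose
    n_total = config.n_patients
    cohort = config.cohort_size

    data = TrialData.empty()
    decisions: list = []
    dose = float(config.initial_dose)
    stopped = False
    cohort_idx = 0
    enrolled = 0
    while enrolled < n_total and not stopped:
        cohort_idx += 1
        size = min(cohort, n_total - enrolled)
        for _ in range(size):
            y = float(response_source(dose))
            data = data.append(dose, y, cohort_idx)
            enrolled += 1
        if check_stopping(data, stopping):
            stopped = True
            break
        if enrolled < n_total:
            step_settings = settings.with_seed(_sampler_seed(settings.seed, cohort_idx))
            if decision_fn is None:
                dose, info = decide(data, config, step_settings, return_details=True)
                info["dose"] = dose
                decisions.append(info)
                logger.info(
                    "n=%d quantile=%.4g options=%s dose=%.4g",
                    info["n"], info["quantile"], info["applied"], dose,
                )
            else:
                dose = float(decide(data, config, step_settings))
                decisions.append({"n": len(data), "dose": dose})
    return TrialResult(
        data=data,
        mtd_estimate=float(data.doses[-1]),
        config=config,
        truth=truth,
        stopped_early=stopped,
        decisions=decisions,
    )


def simulate_trial(
    config: DesignConfig,
    truth: TruthSpec,
    settings: Optional[SamplerSettings] = None,
    seed: Optional[int] = None,
    stopping: Optional[StoppingRule] = None,
) -> TrialResult:
    """Closed-loop simulated trial under a known truth.

    ``seed`` controls both streams: child 0 seeds the response generator,
    child 1 the MCMC chains.
    """
    seed = config.seed if seed is None else seed
    resp_ss, mcmc_ss = np.random.SeedSequence(int(seed) % 2**31).spawn(2)
    rng = np.random.default_rng(resp_ss)
    settings = SamplerSettings() if settings is None else settings
    settings = settings.with_seed(int(mcmc_ss.generate_state(1)[0] % 2**31))
    source = lambda dose: generate_response(dose, truth, config, rng)
    return run_trial(config, source, settings, truth=truth, stopping=stopping)


def interactive_trial(
    config: DesignConfig,
    settings: Optional[SamplerSettings] = None,
    stopping: Optional[StoppingRule] = None,
) -> Generator[float, float, TrialResult]:
    """Generator form of the trial loop for live (non-simulated) use.

    Yields the dose for each patient and expects the observed continuous
    response to be sent back; returns the final ``TrialResult`` on close.
    """
    settings = SamplerSettings() if settings is None else settings
    data = TrialData.empty()
    dose = float(config.initial_dose)
    cohort_idx = 0
    enrolled = 0
    stopped = False
    while enrolled < config.n_patients and not stopped:
        cohort_idx += 1
        size = min(config.cohort_size, config.n_patients - enrolled)
        for _ in range(size):
            y = yield dose
            data = data.append(dose, float(y), cohort_idx)
            enrolled += 1
        if check_stopping(data, stopping):
            stopped = True
            break
        if enrolled < config.n_patients:
            step_settings = settings.with_seed(_sampler_seed(settings.seed, cohort_idx))
            dose = next_dose(data, config, step_settings)
    return TrialResult(
        data=data,
        mtd_estimate=float(data.doses[-1]),
        config=config,
        stopped_early=stopped,
    )
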