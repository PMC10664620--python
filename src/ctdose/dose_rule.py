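"""The dose-finding rule: information set -> next dose.

The base rule assigns the next patient (or cohort) the posterior
``alpha``-quantile of the MTD, which bounds the posterior probability of
overdosing by the feasibility bound ``alpha``.  Three practical variants can
be layered on top, applied in a fixed order on the continuous scale before
snapping to a discrete grid:

1. upper-bounded increment: ``min(x_n + M, q)``;
2. monotone escalation:     ``max(x_n, .)`` (disables de-escalation);
3. discrete dose selection: the nearest grid dose (ties broken downward),
   or — with ``grid_snap="ceiling"`` — the smallest grid dose at or above
   the continuous value, which emulates the conventional practice of
   escalating one dose level as soon as the posterior quantile clears the
   current dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np

from .bayes import PosteriorDraws, posterior_mtd_quantile, sample_posterior
from .config import DesignConfig, SamplerSettings

__all__ = ["TrialData", "StoppingRule", "next_dose", "apply_dose_options", "check_stopping"]


@dataclass
class TrialData:
    """Ordered accrued (dose, response) records.

    Ordering by patient index is the accrual order, so the information sets
    nest: the first ``n`` records are exactly what the rule saw at step ``n``.
    """

    patient_index: np.ndarray
    cohort_index: np.ndarray
    doses: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.patient_index = np.asarray(self.patient_index, dtype=int)
        self.cohort_index = np.asarray(self.cohort_index, dtype=int)
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        n = self.doses.size
        if not (self.patient_index.size == self.cohort_index.size == self.responses.size == n):
            raise ValueError("all record columns must have equal length")
        if n and np.any(np.diff(self.patient_index) <= 0):
            raise ValueError("patient_index must be strictly increasing (accrual order)")

    @classmethod
    def from_arrays(cls, doses, responses, cohort_index=None) -> "TrialData":
        doses = np.asarray(doses, dtype=float)
        responses = np.asarray(responses, dtype=float)
        n = doses.size
        if cohort_index is None:
            cohort_index = np.arange(1, n + 1)
        return cls(np.arange(1, n + 1), cohort_index, doses, responses)

    @classmethod
    def empty(cls) -> "TrialData":
        z = np.empty(0)
        return cls(z, z, z, z)

    def __len__(self) -> int:
        return int(self.doses.size)

    def head(self, n: int) -> "TrialData":
        """The information set after the first ``n`` patients."""
        return TrialData(
            self.patient_index[:n], self.cohort_index[:n],
            self.doses[:n], self.responses[:n],
        )

    def append(self, dose: float, response: float, cohort: int) -> "TrialData":
        nxt = int(self.patient_index[-1]) + 1 if len(self) else 1
        return TrialData(
            np.append(self.patient_index, nxt),
            np.append(self.cohort_index, cohort),
            np.append(self.doses, dose),
            np.append(self.responses, response),
        )

    def validate_doses(self, config: DesignConfig) -> None:
        if len(self) and (np.any(self.doses < config.x_min) or np.any(self.doses >= config.x_max)):
            raise ValueError("doses must lie in [x_min, x_max)")


@dataclass(frozen=True)
class StoppingRule:
    """Safety break: stop once more than ``max_count`` responses reach ``threshold``.

    ``threshold`` plays the role of a severe-toxicity cut (for CTCAE-aligned
    responses, grade >= 4); ``max_count = inf`` disables the rule.
    """

    threshold: float
    max_count: float = math.inf


def check_stopping(data: Optional[TrialData], rule: Optional[StoppingRule]) -> bool:
    """True iff the accrued data trip the stopping predicate."""
    if rule is None or data is None or len(data) == 0:
        return False
    count = int(np.sum(data.responses >= rule.threshold))
    return count > rule.max_count


def _snap_to_grid(value: float, grid: Sequence[float]) -> float:
    """Nearest grid dose; equidistant ties resolve to the lower dose."""
    grid = np.asarray(grid, dtype=float)
    dist = np.abs(grid - value)
    # argmin returns the first minimum; grid is increasing, so ties go low
    return float(grid[int(np.argmin(dist))])


def apply_dose_options(
    quantile: float,
    x_last: float,
    config: DesignConfig,
) -> Tuple[float, dict]:
    """Layer the increment cap, monotone escalation, and grid snap onto ``quantile``."""
    value = quantile
    applied = {}
    if config.max_increment is not None:
        value = min(x_last + config.max_increment, value)
        applied["max_increment"] = value
    if config.monotone:
        value = max(x_last, value)
        applied["monotone"] = value
    if config.dose_grid is not None:
        if config.monotone:
            admissible = [d for d in config.dose_grid if d >= x_last]
            if not admissible:
                raise ValueError(
                    f"no grid dose >= current dose {x_last} is available for "
                    "monotone escalation"
                )
        else:
            admissible = list(config.dose_grid)
        if config.grid_snap == "ceiling":
            at_or_above = [d for d in admissible if d >= value]
            value = at_or_above[0] if at_or_above else admissible[-1]
        else:
            value = _snap_to_grid(value, admissible)
        applied["dose_grid"] = value
    return value, applied


def next_dose(
    data: TrialData,
    config: DesignConfig,
    settings: Optional[SamplerSettings] = None,
    draws: Optional[PosteriorDraws] = None,
    return_details: bool = False,
):
    """Dose for the next patient/cohort given the accrued information set.

    The first dose of a trial is ``config.initial_dose`` and is not produced
    by this rule, so ``data`` must be non-empty.  ``draws`` may be supplied
    to reuse an already-sampled posterior.
    """
    if data is None or len(data) == 0:
        raise ValueError("empty data: the first dose is config.initial_dose")
    data.validate_doses(config)
    if draws is None:
        draws = sample_posterior(data, config, settings)
    quantile = posterior_mtd_quantile(draws, config.alpha)
    x_last = float(data.doses[-1])
    dose, applied = apply_dose_options(quantile, x_last, config)
    if return_details:
        return dose, {"n": len(data), "quantile": quantile, "applied": applied}
    return dose
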