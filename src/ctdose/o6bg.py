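"""Re-design of the O6-benzylguanine (O6-BG) dose-escalation trial.

O6-BG is a molecularly targeted agent whose biological effect is depletion
of the DNA-repair enzyme O6-alkylguanine-DNA alkyltransferase (AGT,
activity in fmol/mg).  In the original trial, 24 patients received doses of
40, 60, 80 or 100 mg/m^2 (3, 3, 9 and 9 patients respectively) and tumor
AGT activity was recorded; activity below 5 fmol/mg counts as undetectable
and is the target event.  Lower AGT means a stronger drug effect, so the
continuous response used for dose finding is the monotone transform
``60 - AGT``; the undetectable-activity event ``AGT < 5`` then corresponds
to a transformed response above the threshold 55.

This module packages the recorded activities, the transform, the
least-squares power fit of the dose-response curve, a perturbation
resampler that emulates new patients at each dose level, and the
cohort-sequential Bayesian re-design of the trial.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .config import DesignConfig, SamplerSettings
from .curvefit import fit_power_curve
from .trial import TrialResult, run_trial

__all__ = [
    "AGT_POOLS",
    "PERTURBATION_BOUNDS",
    "AGT_DETECTION_LIMIT",
    "agt_dataset",
    "transform_agt",
    "count_below_threshold",
    "fit_agt_power_curve",
    "resample_with_perturbation",
    "redesign_config",
    "run_redesign",
    "load_trajectory",
]

#: Recorded tumor AGT activity (fmol/mg) by assigned dose (mg/m^2).
AGT_POOLS = {
    40.0: (26.35, 42.00, 15.00),
    60.0: (23.00, 13.50, 11.00),
    80.0: (31.67, 8.00, 9.00, 14.50, 11.50, 7.00, 11.70, 9.03, 8.00),
    100.0: (4.07, 5.00, 8.70, 2.50, 4.07, 6.13, 3.60, 5.00, 5.00),
}

#: Half-width (fmol/mg) of the uniform perturbation added when resampling a
#: patient at each dose; the observed response spread shrinks as dose grows.
PERTURBATION_BOUNDS = {40.0: 8.0, 60.0: 6.0, 80.0: 4.0, 100.0: 2.0}

#: AGT activity below this limit is undetectable (the target event).
AGT_DETECTION_LIMIT = 5.0

#: Transformed-response threshold equivalent to the detection limit.
RESPONSE_THRESHOLD = 60.0 - AGT_DETECTION_LIMIT


def agt_dataset() -> pd.DataFrame:
    """The 24 recorded patients as (dose, agt_activity, response) rows."""
    rows = [
        (dose, agt) for dose, pool in AGT_POOLS.items() for agt in pool
    ]
    df = pd.DataFrame(rows, columns=["dose", "agt_activity"])
    df["response"] = transform_agt(df["agt_activity"].to_numpy())
    return df


def transform_agt(agt):
    """Continuous response ``60 - AGT``; monotone decreasing in activity."""
    agt = np.asarray(agt, dtype=float)
    if np.any(agt < 0):
        raise ValueError("AGT activity cannot be negative")
    out = 60.0 - agt
    return float(out) if out.ndim == 0 else out


def count_below_threshold(agt_values, threshold: float = AGT_DETECTION_LIMIT) -> int:
    """Number of activities strictly below ``threshold`` (undetectable count)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    agt = np.asarray(agt_values, dtype=float)
    return int(np.sum(agt < threshold))


def fit_agt_power_curve(x_min: float = 20.0) -> tuple[float, float]:
    """Least-squares ``(beta_hat, nu_hat)`` of ``y = beta (x - x_min)^nu``
    on the 24 transformed responses."""
    df = agt_dataset()
    return fit_power_curve(df["dose"], df["response"], x_min=x_min)


def resample_with_perturbation(
    dose: float,
    rng: np.random.Generator,
    noise_bound: Optional[float] = None,
) -> float:
    """Emulate a new patient at ``dose``: resample one recorded AGT value and
    add Uniform(-b, +b) noise with the dose-specific bound ``b``.

    The result is floored at zero (activity cannot be negative).  Dose
    120 mg/m^2 had no patients; it borrows the dose-100 pool with the
    tightest bound and emits a warning.  ``noise_bound`` overrides the
    dose-specific bound (0 suppresses the noise entirely).
    """
    dose = float(dose)
    if dose == 120.0:
        warnings.warn(
            "dose 120 mg/m^2 has no recorded patients; resampling from the "
            "dose-100 pool with its perturbation bound",
            RuntimeWarning,
        )
        pool_dose = 100.0
    elif dose in AGT_POOLS:
        pool_dose = dose
    else:
        raise ValueError(f"unsupported dose {dose}: no recorded response pool")
    pool = AGT_POOLS[pool_dose]
    bound = PERTURBATION_BOUNDS[pool_dose] if noise_bound is None else float(noise_bound)
    agt = pool[int(rng.integers(len(pool)))]
    if bound > 0:
        agt += rng.uniform(-bound, bound)
    return max(agt, 0.0)


def redesign_config(variant: Literal["accelerated", "standard"]) -> DesignConfig:
    """Design constants of the cohort-sequential O6-BG re-design.

    Both variants enroll 30 patients in cohorts of three over the dose grid
    {40, 60, 80, 100, 120} mg/m^2 with monotone escalation; they differ only
    in the feasibility bound (0.1 accelerated, 0.05 standard).  Grid
    selection uses the ceiling snap — the trial escalates one level as soon
    as the posterior quantile clears the current dose, the conventional
    one-level escalation practice for discrete dose levels.
    """
    if variant not in ("accelerated", "standard"):
        raise ValueError("variant must be 'accelerated' or 'standard'")
    return DesignConfig(
        eta=RESPONSE_THRESHOLD,
        gamma=0.6,
        x_min=20.0,
        x_max=140.0,
        delta=0.5,
        alpha=0.1 if variant == "accelerated" else 0.05,
        initial_dose=40.0,
        n_patients=30,
        cohort_size=3,
        dose_grid=(40.0, 60.0, 80.0, 100.0, 120.0),
        grid_snap="ceiling",
        monotone=True,
    )


def run_redesign(
    variant: Literal["accelerated", "standard"],
    seed: int = 0,
    settings: Optional[SamplerSettings] = None,
) -> TrialResult:
    """One replicate of the Bayesian re-design with resampled responses.

    Patient responses are produced by ``resample_with_perturbation`` followed
    by the ``60 - AGT`` transform; the dose of the final cohort is the
    optimal-dose estimate.
    """
    config = redesign_config(variant)
    resp_ss, mcmc_ss = np.random.SeedSequence(int(seed) % 2**31).spawn(2)
    rng = np.random.default_rng(resp_ss)
    settings = SamplerSettings() if settings is None else settings
    settings = settings.with_seed(int(mcmc_ss.generate_state(1)[0] % 2**31))

    def source(dose: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            agt = resample_with_perturbation(dose, rng)
        return float(transform_agt(agt))

    return run_trial(config, source, settings)


def load_trajectory(variant: Literal["accelerated", "standard"]) -> pd.DataFrame:
    """The published 30-patient re-design trajectory for a variant.

    Columns: patient, cohort, dose (mg/m^2), agt_activity (fmol/mg),
    response (``60 - AGT``).
    """
    if variant not in ("accelerated", "standard"):
        raise ValueError("variant must be 'accelerated' or 'standard'")
    ref = resources.files("ctdose.data").joinpath(f"o6bg_trajectory_{variant}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
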