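"""Operating-characteristic metrics and replicated trial experiments.

Four metrics summarise a finished (or interim) trial against a known truth:

* ``NPD(n)``  -- number of patients with a DLT, ``#{i <= n : y_i >= eta}``;
* ``NPO(n)``  -- number of patients overdosed, ``#{i <= n : x_i > xi0}``;
* ``BTM(n)``  -- bias to the true MTD of the current dose, ``x_n - xi0``;
* ``RMSE(n)`` -- relative absolute error ``|x_n - xi0| / xi0`` (the square
  root of the relative squared error of a single trial).

NPD and NPO measure safety; BTM and RMSE measure estimation accuracy.  A
rule whose replicated BTM is positive escalates past the true MTD and is
unsafe.  ``replicate_experiment`` repeats independent simulated trials and
reports medians of the four metrics (plus quartiles and per-replicate
records for uncertainty assessment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import DesignConfig, SamplerSettings, TruthSpec
from .trial import TrialResult, simulate_trial

__all__ = [
    "compute_metrics",
    "replicate_experiment",
    "ReplicationSummary",
    "bootstrap_median_ci",
]


def compute_metrics(
    result: TrialResult,
    truth: TruthSpec,
    config: DesignConfig,
    n: Optional[int] = None,
    dlt_strict: bool = False,
) -> dict:
    """The four metrics after the first ``n`` patients (default: all).

    ``dlt_strict`` switches the DLT count from the generic ``y >= eta``
    convention to the strict ``y > eta`` one used when the threshold itself
    is an attainable value (as in the enzyme-activity case study).
    """
    total = len(result.data)
    if n is None:
        n = total
    if not 1 <= n <= total:
        raise ValueError(f"n must lie in [1, {total}], got {n}")
    y = result.responses[:n]
    x = result.doses[:n]
    npd = int(np.sum(y > config.eta) if dlt_strict else np.sum(y >= config.eta))
    npo = int(np.sum(x > truth.xi0))
    btm = float(x[-1] - truth.xi0)
    rmse = float(abs(x[-1] - truth.xi0) / truth.xi0)
    return {"NPD": npd, "NPO": npo, "BTM": btm, "RMSE": rmse}


@dataclass
class ReplicationSummary:
    """Medians and per-replicate records from a replicated experiment."""

    table: pd.DataFrame
    medians: dict
    quartiles: pd.DataFrame

    def bootstrap_median_ci(
        self, metric: str, n_boot: int = 2000, level: float = 0.95, seed: int = 0
    ) -> Tuple[float, float]:
        return bootstrap_median_ci(
            self.table[metric].to_numpy(), n_boot=n_boot, level=level, seed=seed
        )


def replicate_experiment(
    config: DesignConfig,
    truth: TruthSpec,
    n_reps: int,
    settings: Optional[SamplerSettings] = None,
    seed: Optional[int] = None,
) -> ReplicationSummary:
    """Run ``n_reps`` independent simulated trials and summarise the metrics.

    Each replicate gets a distinct child seed spawned from the master seed,
    so the whole experiment is reproducible.  The median convention for even
    replicate counts is the midpoint of the two central order statistics
    (numpy's default).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seed = config.seed if seed is None else seed
    children = np.random.SeedSequence(int(seed) % 2**31).spawn(n_reps)
    rows = []
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        try:
            result = simulate_trial(config, truth, settings=settings, seed=rep_seed)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"replicate {rep} failed") from exc
        m = compute_metrics(result, truth, config)
        m["rep"] = rep
        m["seed"] = rep_seed
        m["final_dose"] = result.mtd_estimate
        rows.append(m)
    table = pd.DataFrame(rows).set_index("rep")
    metric_cols = ["NPD", "NPO", "BTM", "RMSE"]
    medians = {c: float(np.median(table[c])) for c in metric_cols}
    quartiles = table[metric_cols].quantile([0.25, 0.5, 0.75])
    return ReplicationSummary(table=table, medians=medians, quartiles=quartiles)


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> Tuple[float, float]:
    """Percentile bootstrap interval for the median of ``values``."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.quantile(medians, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
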