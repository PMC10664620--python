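"""Configuration and trial-record persistence.

Configs round-trip through JSON or YAML with the ``DesignConfig`` field
names; trial records round-trip through CSV with the header
``patient,cohort,dose,response``.  Loading re-validates all type
invariants, so a malformed file fails loudly with a field diagnostic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .config import DesignConfig
from .dose_rule import TrialData
from .trial import TrialResult

__all__ = ["load_config", "save_config", "save_trial", "load_trial"]

PathLike = Union[str, Path]

TRIAL_COLUMNS = ["patient", "cohort", "dose", "response"]


def load_config(path: PathLike) -> DesignConfig:
    """Read a design configuration from a ``.json``/``.yaml``/``.yml`` file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"malformed config file {path}: expected a mapping")
    try:
        return DesignConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config in {path}: {exc}") from exc


def save_config(config: DesignConfig, path: PathLike) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def save_trial(result: Union[TrialResult, TrialData], path: PathLike) -> None:
    """Write trial records as CSV with header ``patient,cohort,dose,response``."""
    data = result.data if isinstance(result, TrialResult) else result
    df = pd.DataFrame(
        {
            "patient": data.patient_index,
            "cohort": data.cohort_index,
            "dose": data.doses,
            "response": data.responses,
        }
    )
    df.to_csv(path, index=False)


def load_trial(path: PathLike, config: DesignConfig | None = None) -> TrialData:
    """Read trial records, validating ordering and (optionally) dose range."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise ValueError(f"malformed trial file {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed trial file {path}: missing columns {missing}")
    for col in TRIAL_COLUMNS:
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 2  # header + 1-based
            raise ValueError(f"malformed trial file {path}: empty '{col}' at line {row}")
    data = TrialData(
        df["patient"].to_numpy(),
        df["cohort"].to_numpy(),
        df["dose"].to_numpy(),
        df["response"].to_numpy(),
    )
    if config is not None:
        data.validate_doses(config)
    return data
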