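"""File formats: trial-log CSV, parameter and condition configs, sidecars.

Trial logs are comma-separated UTF-8 with a mandatory header and the
columns (session, trial, chosen_option, chosen_location, item_label);
(session, trial) must be unique and gap-free.  JSON outputs are
pretty-printed with sorted keys.  Every artifact written by the CLI
carries a sidecar with the tool version, a config hash and the seeds,
so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import InvalidInputError
from .rl_core import ModelParams
from .task_library import ConditionSpec

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "read_params",
    "write_params",
    "read_condition",
    "write_condition",
    "write_json",
    "read_json",
    "config_hash",
    "sidecar",
]

TRIAL_LOG_COLUMNS = ("session", "trial", "chosen_option", "chosen_location", "item_label")


def validate_trial_log(df: pd.DataFrame, alphabet=None) -> pd.DataFrame:
    """Schema-check a trial log; raises naming the offending row/column."""
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"trial log missing column(s) {missing}")
    for col in ("session", "trial"):
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric < 1) | (numeric != numeric.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InvalidInputError(
                f"column {col!r}, row {row}: value {vals.iloc[row]!r} is not a positive integer"
            )
        df[col] = numeric.astype(int)
    for sess, grp in df.groupby("session", sort=True):
        trials = grp["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, trials.size + 1)):
            raise InvalidInputError(
                f"session {sess}: trial numbers are not gap-free 1..{trials.size}"
            )
    if alphabet is not None:
        allowed = set(alphabet)
        for row, label in enumerate(df["chosen_option"]):
            if label not in allowed:
                raise InvalidInputError(
                    f"row {row}: label {label!r} outside the option alphabet {sorted(allowed)}"
                )
    return df


def read_trial_log(path, alphabet=None) -> pd.DataFrame:
    """Read and strictly validate a trial-log CSV (never silently coerces)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return validate_trial_log(df, alphabet)


def write_trial_log(df: pd.DataFrame, path) -> None:
    validate_trial_log(df.copy())
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _load_by_suffix(path):
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_params(path) -> ModelParams:
    """Load ModelParams from a JSON or YAML mapping."""
    d = _load_by_suffix(path)
    try:
        return ModelParams.from_dict(d)
    except TypeError as e:
        raise InvalidInputError(f"bad parameter file {path}: {e}") from None


def write_params(params: ModelParams, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        write_json(d, path)


def read_condition(path) -> ConditionSpec:
    """Load a condition spec from YAML/JSON (round-trips write_condition)."""
    d = _load_by_suffix(path)
    try:
        return ConditionSpec.from_dict(d)
    except (TypeError, KeyError) as e:
        raise InvalidInputError(f"bad condition file {path}: {e}") from None


def write_condition(spec: ConditionSpec, path) -> None:
    path = Path(path)
    d = spec.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        write_json(d, path)


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def sidecar(config: dict, seeds: dict) -> dict:
    """Provenance record embedded next to every output artifact."""
    return {
        "tool": "attnrl",
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "seeds": seeds,
    }
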