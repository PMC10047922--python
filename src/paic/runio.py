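"""Configuration loading, result serialization and seeding helpers.

YAML for human-written configs, JSON for machine-readable results, CSV for
tables.  All writes are atomic (temp file in the target directory, then
rename) so an interrupted run never leaves a partial file at the target
path.
"""
from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .conjugate import StudyConfig
from .hierlogit import LogitConfig

SCHEMA_VERSION = 1
COMMANDS = ("compute", "normal-study", "logit-experiment")
_STOCHASTIC = ("normal-study", "logit-experiment")


def _package_version() -> str:
    try:
        return version("paic")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """A validated run configuration for one CLI command."""

    command: str
    seed: Optional[int]
    params: dict
    output: Optional[str] = None
    verbosity: int = 0

    def experiment_config(self):
        """Materialise the concrete config object for the command."""
        if self.command == "logit-experiment":
            return LogitConfig(seed=self.seed, **self.params)
        if self.command == "normal-study":
            return StudyConfig(seed=self.seed, **self.params)
        raise ValueError(f"command {self.command!r} has no experiment config")


def _allowed_keys(command: str) -> set[str]:
    if command == "logit-experiment":
        cfg = LogitConfig
    elif command == "normal-study":
        cfg = StudyConfig
    else:
        return {"seed", "draws", "model", "model_config", "criteria"}
    return {f.name for f in dataclasses.fields(cfg)}


def load_config(path, command: str) -> RunConfig:
    """Load and validate a YAML config for ``command``.

    Defaults for unspecified keys are the experiment defaults (N=15,
    n_i=50, the weakly informative hyperprior, 3 chains, 1-in-5 thinning).

    Raises
    ------
    ValueError
        For an unknown command, an unknown key (named explicitly), a
        missing seed on a stochastic command, or non-positive sizes
        (raised by the config dataclass).
    """
    if command not in COMMANDS:
        raise ValueError(f"unknown command {command!r}")
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    allowed = _allowed_keys(command)
    for key in raw:
        if key not in allowed:
            raise ValueError(
                f"unknown configuration key {key!r} for command {command!r}"
            )
    seed = raw.pop("seed", None)
    if seed is None and command in _STOCHASTIC:
        raise ValueError(f"stochastic command {command!r} requires a seed")
    return RunConfig(command=command, seed=seed, params=raw)


def save_config(cfg: RunConfig, path) -> None:
    payload = {"seed": cfg.seed, **cfg.params}
    _atomic_write_text(path, yaml.safe_dump(payload, sort_keys=True))


# ---------------------------------------------------------------------------
# results


@dataclass
class ResultRecord:
    """A serialisable record of one run: config echo + results + metadata."""

    command: str
    seed: Optional[int]
    config: dict
    results: Any
    schema_version: int = SCHEMA_VERSION
    package_version: str = field(default_factory=_package_version)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "package_version": self.package_version,
            "command": self.command,
            "seed": self.seed,
            "config": _jsonable(self.config),
            "results": _jsonable(self.results),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResultRecord":
        rec = cls(
            command=d["command"],
            seed=d["seed"],
            config=d["config"],
            results=d["results"],
        )
        rec.schema_version = d["schema_version"]
        rec.package_version = d["package_version"]
        return rec


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def _atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_results(record: ResultRecord, path) -> None:
    """Write a JSON result record atomically."""
    _atomic_write_text(path, json.dumps(record.to_dict(), indent=2))


def load_results(path) -> ResultRecord:
    with open(path) as fh:
        return ResultRecord.from_dict(json.load(fh))


def save_table(df: pd.DataFrame, path) -> None:
    """Write a CSV table atomically with a stable column order."""
    _atomic_write_text(path, df.to_csv(index=False))
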