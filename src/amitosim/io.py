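"""Configuration parsing, trajectory/manifest writers and logging setup."""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .model import SimParams

__all__ = [
    "SCHEMA_VERSION",
    "RunManifest",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "setup_logging",
]

SCHEMA_VERSION = 1

logger = logging.getLogger("amitosim")

_PARAM_FIELDS = {f.name for f in dataclasses.fields(SimParams)}
_INT_FIELDS = {"I", "M", "pop_size", "n_iter", "seed"}


def setup_logging(level: int = logging.INFO) -> None:
    """Configure a plain stderr log handler for the package logger."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def _read_mapping(path: Path) -> dict:
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text()) or {}
    elif suffix == ".toml":
        data = tomllib.loads(path.read_text())
    elif suffix == ".json":
        data = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r} (use YAML, TOML or JSON)")
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def load_config(path: str | Path) -> SimParams:
    """Load simulation parameters, filling missing fields with the defaults.

    Unknown keys (e.g. per-cell properties like ``E``, which are not
    configurable) and type mismatches are rejected with the offending
    field named; range violations surface as ``ValueError`` from
    :class:`~amitosim.model.SimParams`.
    """
    path = Path(path)
    data = _read_mapping(path)
    unknown = set(data) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, val in data.items():
        if isinstance(val, bool) or not isinstance(val, (int, float)):
            raise ValueError(f"config key {key!r} must be a number, got {val!r}")
        coerced[key] = int(val) if key in _INT_FIELDS else float(val)
    return SimParams(**coerced)


def write_trajectory(summaries, path: str | Path) -> Path:
    """Write recorded population summaries as CSV (full float precision).

    Accepts either a list of PopulationSummary or a DataFrame; the column
    order is fixed by the summary schema and a header row is always
    written.  Round-trips bit-exactly through :func:`read_trajectory`.
    """
    if isinstance(summaries, pd.DataFrame):
        frame = summaries
    else:
        frame = pd.DataFrame([s.__dict__ for s in summaries])
    if len(frame) == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    return pd.read_csv(path)


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record for one simulation run.

    Holds everything needed to regenerate the trajectory (params + seed),
    plus end-state and convergence summaries and paths to the artifacts
    written alongside it.  Round-trips losslessly through JSON.
    """

    params: dict
    seed: int
    started: str
    finished: str
    end_state: dict
    convergence: dict
    artifacts: dict
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def create(cls, params: SimParams, end_state: dict, convergence: dict, artifacts: dict,
               started: datetime, finished: datetime) -> "RunManifest":
        return cls(
            params=dataclasses.asdict(params),
            seed=params.seed,
            started=started.astimezone(timezone.utc).isoformat(),
            finished=finished.astimezone(timezone.utc).isoformat(),
            end_state=end_state,
            convergence=convergence,
            artifacts=artifacts,
        )

    def params_obj(self) -> SimParams:
        return SimParams(**self.params)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported manifest schema: {data.get('schema_version')}")
        return cls(**data)
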