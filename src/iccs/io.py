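"""Configuration loading and game-log CSV I/O.

Game logs are plain CSV, UTF-8, "." decimal, one row per trial, preceded by
``#``-prefixed provenance comments carrying the schema version, the seed,
the condition label, and a JSON echo of every model parameter (premiums
included, so downstream analyses are premium-explicit).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .model import GAMELOG_SCHEMA_VERSION, LOG_COLUMNS, GameLog
from .params import ModelParams

_MAGIC = "# iccs-gamelog"


class SchemaVersionError(ValueError):
    """A log file's schema version does not match this package's."""


def load_params(path: str | Path) -> ModelParams:
    """Read a YAML or JSON parameter file; unknown keys are rejected."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"parameter file {path} must contain a mapping")
    return ModelParams.from_dict(data)


def write_gamelog(log: GameLog, path: str | Path) -> None:
    """Write a game log as commented CSV (schema v{GAMELOG_SCHEMA_VERSION})."""
    path = Path(path)
    header = [
        f"{_MAGIC} v{log.meta['schema_version']}",
        f"# seed={log.meta['seed']}",
        f"# condition={log.meta['condition']}",
        f"# params={json.dumps(log.meta['params'], sort_keys=True)}",
        f"# columns={','.join(LOG_COLUMNS)}",
    ]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(header) + "\n")
        log.table.to_csv(fh, index=False)


def read_gamelog(path: str | Path) -> GameLog:
    """Read a game log written by :func:`write_gamelog`.

    Raises :class:`SchemaVersionError` if the file was written under a
    different schema version (explicit migration is required rather than a
    silent misread).
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(_MAGIC):
            raise SchemaVersionError(
                f"{path} is not an iccs game log (missing '{_MAGIC}' header)"
            )
        version = first[len(_MAGIC) :].strip()
        if version != f"v{GAMELOG_SCHEMA_VERSION}":
            raise SchemaVersionError(
                f"{path} has schema {version}, this package reads "
                f"v{GAMELOG_SCHEMA_VERSION}; migrate the log first"
            )
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value
    table = pd.read_csv(path, comment="#")
    params = json.loads(meta["params"]) if "params" in meta else None
    return GameLog(
        table=table,
        meta={
            "schema_version": GAMELOG_SCHEMA_VERSION,
            "seed": meta.get("seed", ""),
            "condition": meta.get("condition", ""),
            "params": params,
        },
    )


def write_provenance(path: str | Path, payload: dict[str, Any]) -> None:
    """Write a JSON provenance sidecar (params echo, seed, version, ...)."""
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )


def load_yaml(path: str | Path) -> dict[str, Any]:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a mapping")
    return data
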