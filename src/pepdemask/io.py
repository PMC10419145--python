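"""CSV/JSON/YAML interchange helpers and provenance logging."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .kinetics import ConcentrationCurve

FLOAT_FORMAT = "%.6g"

_CONFIG_KEYS = {
    "substrate_map",
    "rate_overrides",
    "mechanism",
    "kdf",
    "kd",
    "ki",
    "kj",
    "time_grid",
    "degree_grid",
    "noise_sd",
    "seed",
    "absolute_scale",
    "output_dir",
    "verbosity",
}


class ConfigError(ValueError):
    """Raised for configs with unknown or malformed keys."""


def curves_to_frame(curves: Iterable[ConcentrationCurve]) -> pd.DataFrame:
    """Tidy (species, axis, grid_value, concentration) table of curves."""
    records = [
        {
            "species": curve.species,
            "axis": curve.axis,
            "grid_value": g,
            "concentration": v,
        }
        for curve in curves
        for g, v in zip(curve.grid, curve.values)
    ]
    return pd.DataFrame.from_records(records)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_json(payload: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML/JSON run configuration."""
    text = Path(path).read_text()
    payload = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    if not isinstance(payload, dict):
        raise ConfigError("config must be a mapping")
    unknown = sorted(set(payload) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; allowed: {sorted(_CONFIG_KEYS)}"
        )
    if "rate_overrides" in payload:
        payload["rate_overrides"] = {
            int(k): float(v) for k, v in dict(payload["rate_overrides"]).items()
        }
    return payload


def provenance_record(
    config: Mapping, *, corrections: Iterable[str] = ()
) -> dict:
    """A reproducibility stamp: config hash, package version, corrections."""
    from . import __version__

    digest = hashlib.sha256(
        json.dumps(dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "package": "pepdemask",
        "version": __version__,
        "config_sha256": digest,
        "config": {k: config[k] for k in sorted(config, key=str)},
        "corrections": list(corrections),
    }
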