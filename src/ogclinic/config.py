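"""Configuration loading and clock arithmetic.

The clinic is described by a nested mapping (YAML on disk, JSON accepted):
daily volumes, attribute rates, per-(station, class) service-time quartiles,
resource counts, timing constants and the calibrated downtime process.  A user
file is deep-merged over the packaged defaults, so partial overrides are
enough.
"""

from __future__ import annotations

import copy
import importlib.resources
import json
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "hhmm_to_minutes", "minutes_to_hhmm"]


def hhmm_to_minutes(value) -> float:
    """Parse 'HH:MM' (or a bare number of minutes) into clock-minutes."""
    if isinstance(value, (int, float)):
        return float(value)
    h, m = str(value).split(":")
    return 60.0 * int(h) + float(m)


def minutes_to_hhmm(minutes: float) -> str:
    minutes = int(round(minutes)) % 1440
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def default_config() -> dict:
    text = importlib.resources.files("ogclinic.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load the default configuration, optionally overridden by a YAML/JSON file."""
    cfg = default_config()
    if path is None:
        return cfg
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        user = json.loads(text)
    else:
        user = yaml.safe_load(text)
    if not isinstance(user, dict):
        raise ValueError(f"configuration file {path} did not parse to a mapping")
    return _deep_merge(cfg, user)


def service_spec(config: dict, station: str, klass: str) -> tuple[float, float, float]:
    """The (q1, median, q3) triple for a (station, patient class) pair."""
    table = config["service_times"].get(station)
    if table is None:
        raise KeyError(f"no service-time block for station {station!r}")
    row = table.get(klass, table.get("default"))
    if row is None:
        raise KeyError(f"no service-time spec for class {klass!r} at station {station!r}")
    q1, med, q3 = (float(x) for x in row)
    return q1, med, q3
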