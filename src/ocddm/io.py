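"""Configuration loading and provenance helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["load_config", "config_hash", "write_json"]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return out


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration dict (embedded in outputs so a
    run can be matched to the exact settings that produced it)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(path: str | Path, payload: dict, config: dict | None = None) -> None:
    if config is not None:
        payload = dict(payload)
        payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
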