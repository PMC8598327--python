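"""Run configuration: YAML/JSON files with CLI-flag overrides."""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace

import yaml

from .cascade import DSNConfig, _config_from_dict, _config_to_dict
from .scanning import ScanConfig

__all__ = ["load_run_config", "config_hash"]

_SCAN_KEYS = {"windows", "stride", "padded", "forests_per_window"}


def load_run_config(path=None, overrides: dict | None = None) -> DSNConfig:
    """Build a :class:`DSNConfig` from an optional YAML/JSON file plus overrides.

    File keys mirror the DSNConfig fields; scan geometry may be given either
    nested under ``scan:`` or flat (``windows``, ``stride``, ``padded``,
    ``forests_per_window``).  Overrides (CLI flags) win over file values;
    ``None`` overrides are ignored.
    """
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    flat_scan = {k: data.pop(k) for k in list(data) if k in _SCAN_KEYS}
    scan_data = dict(data.pop("scan", {}) or {})
    scan_data.update(flat_scan)

    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key in _SCAN_KEYS:
            scan_data[key] = value
        else:
            data[key] = value

    cfg = DSNConfig(**data)
    if scan_data:
        if "windows" in scan_data:
            scan_data["windows"] = tuple(scan_data["windows"])
        cfg = replace(cfg, scan=replace(ScanConfig(), **scan_data))
    return cfg


def config_hash(cfg: DSNConfig) -> str:
    """Stable short hash of a configuration, for log provenance."""
    payload = json.dumps(_config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def config_to_dict(cfg: DSNConfig) -> dict:
    return _config_to_dict(cfg)


def config_from_dict(d: dict) -> DSNConfig:
    return _config_from_dict(d)
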