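"""Configuration: JSON/YAML blocks for medium, source and protocol.

Every default is overridable from a config file with top-level ``medium``,
``source`` and ``protocol`` blocks, e.g.::

    medium:
      thermal_conductivity: 0.6
      volumetric_heat_capacity: 4.18e6
    source:
      geometry: gaussian_spheroid
      lateral_radius_um: 1.0
      axial_radius_um: 2.0
    protocol:
      mode: pulsed
      repetition_frequency_hz: 1000
      pulse_length_ms: 0.2
      ambient_temperature_c: 23
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .heat_model import LaserProtocol, Medium, SourceModel

_MEDIUM_KEYS = {
    "thermal_conductivity",
    "volumetric_heat_capacity",
    "thermal_diffusivity",
    "absorption_coefficient",
}
_SOURCE_KEYS = {"geometry", "lateral_radius_um", "axial_radius_um"}
_PROTOCOL_KEYS = {
    "mode",
    "incident_power_mw",
    "absorbed_fraction",
    "repetition_frequency_hz",
    "pulse_length_ms",
    "session_duration_s",
    "ambient_temperature_c",
}


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _build(cls, block: dict, allowed: set[str]):
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} config keys: {sorted(unknown)}")
    return cls(**block)


def medium_from_config(config: dict) -> Medium:
    return _build(Medium, dict(config.get("medium", {})), _MEDIUM_KEYS)


def source_from_config(config: dict) -> SourceModel:
    return _build(SourceModel, dict(config.get("source", {})), _SOURCE_KEYS)


def protocol_from_config(config: dict) -> LaserProtocol:
    return _build(LaserProtocol, dict(config.get("protocol", {})), _PROTOCOL_KEYS)


def default_config() -> dict:
    return {
        "medium": asdict(Medium.water()),
        "source": asdict(SourceModel()),
        "protocol": asdict(LaserProtocol()),
    }
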