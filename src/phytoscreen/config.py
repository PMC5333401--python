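"""Run configuration: one JSON/YAML file shared by all commands."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .plates import PlateLayout
from .roots import SegmentationConfig
from .simulate import WellGeometry

__all__ = ["load_config", "geometry_from", "layout_from", "segmentation_from"]


def load_config(path: str | Path | None) -> dict:
    """Load a JSON or YAML config file; ``None`` yields an empty config."""
    if path is None:
        return {}
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def geometry_from(config: dict) -> WellGeometry:
    return WellGeometry(**config.get("geometry", {}))


def layout_from(config: dict) -> PlateLayout:
    sub = dict(config.get("layout", {}))
    if "control_strip_positions" in sub:
        sub["control_strip_positions"] = frozenset(sub["control_strip_positions"])
    return PlateLayout(**sub)


def segmentation_from(config: dict) -> SegmentationConfig:
    sub = dict(config.get("segmentation", {}))
    if "ridge_sigmas" in sub:
        sub["ridge_sigmas"] = tuple(sub["ridge_sigmas"])
    return SegmentationConfig(**sub)
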