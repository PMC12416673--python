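"""YAML run configuration: sim / model / loss / train sections.

Precedence is CLI flag > config file > built-in default; the resolved
configuration is snapshotted into every run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .network import ModelConfig
from .objective import LossConfig
from .synthfundus import SimConfig
from .trainer import TrainConfig

SECTIONS = ("sim", "model", "loss", "train", "data")


def load_config(path=None) -> dict:
    cfg: dict = {s: {} for s in SECTIONS}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        for key, value in loaded.items():
            if key not in SECTIONS:
                raise ValueError(f"unknown config section {key!r}")
            cfg[key].update(value or {})
    return cfg


def apply_overrides(cfg: dict, overrides: dict) -> dict:
    """Merge ``{"section.key": value}`` flag overrides into a config."""
    for dotted, value in overrides.items():
        if value is None:
            continue
        section, _, key = dotted.partition(".")
        if section not in SECTIONS or not key:
            raise ValueError(f"unknown override {dotted!r}")
        cfg[section][key] = value
    return cfg


def _build(dc_cls, section: dict):
    known = {k: v for k, v in section.items()
             if k in dc_cls.__dataclass_fields__}
    unknown = set(section) - set(known)
    if unknown:
        raise ValueError(
            f"unknown {dc_cls.__name__} fields: {sorted(unknown)}")
    obj = dc_cls(**known)
    return obj.validate() if hasattr(obj, "validate") else obj


def sim_config(cfg: dict) -> SimConfig:
    return _build(SimConfig, cfg.get("sim", {}))


def model_config(cfg: dict) -> ModelConfig:
    section = dict(cfg.get("model", {}))
    for key in ("growth_rates", "layers_per_block", "stage_channels"):
        if key in section:
            section[key] = tuple(section[key])
    return _build(ModelConfig, section)


def loss_config(cfg: dict) -> LossConfig:
    return _build(LossConfig, cfg.get("loss", {}))


def train_config(cfg: dict) -> TrainConfig:
    return _build(TrainConfig, cfg.get("train", {}))


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
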