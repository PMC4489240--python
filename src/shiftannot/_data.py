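"""Loaders for the versioned data tables shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=None)
def load_table(name: str) -> dict:
    text = resources.files("shiftannot").joinpath("data", name).read_text()
    return yaml.safe_load(text)


def random_coil_shifts() -> dict:
    return load_table("random_coil.yaml")


def csi_thresholds() -> dict[str, float]:
    return dict(load_table("csi_thresholds.yaml")["thresholds"])


def canonical_turn_angles() -> dict[str, tuple[float, float, float, float]]:
    raw = load_table("turn_angles.yaml")["canonical_turn_angles"]
    return {k: tuple(float(x) for x in v) for k, v in raw.items()}


def hydropathy_scale() -> dict[str, float]:
    return dict(load_table("hydropathy.yaml")["scale"])


def turn_propensity() -> dict[str, dict[str, str]]:
    return dict(load_table("turn_propensity.yaml")["propensity"])


def generator_model_defaults() -> dict:
    return load_table("generator_model.yaml")
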