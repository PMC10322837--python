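"""YAML configuration loading for the CLI.

A config file may carry any of three sections; every field is optional and
falls back to the documented default:

.. code-block:: yaml

    burden:
      tumor_channel: hematoxylin
      normal_channel: eosin
      smoothing_sigma_px: 1.0
      min_object_diameter_px: 5.0
      stain_basis:
        hematoxylin: [0.650, 0.704, 0.286]
        eosin: [0.072, 0.990, 0.105]
    coloc:
      nuclei: {typical_diameter_px: [6, 40], smoothing_sigma_px: 1.0, discard_border: true}
      edu:    {typical_diameter_px: [6, 40], discard_border: false}
      uhrf1:  {typical_diameter_px: [6, 40], discard_border: false}
    simulate:
      he:    {target_tumor_fraction: 0.30}
      fluor: {n_nuclei: 300, p_edu: 0.40, p_uhrf1: 0.30, p_both: 0.20}
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .burden import BurdenConfig
from .coloc import DEFAULT_CHANNEL_CONFIGS, ChannelConfig
from .errors import ConfigError
from .simulate import SynthFluorParams, SynthHEParams
from .unmixing import StainBasis

__all__ = [
    "load_config",
    "burden_config",
    "channel_configs",
    "he_params",
    "fluor_params",
    "defaults_as_dict",
]


def load_config(path) -> dict:
    """Parse a YAML config file into a plain dict ({} for no file)."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def _build(cls, section: dict, where: str, **overrides):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"{where}: unknown field(s) {sorted(unknown)}")
    kwargs = dict(section)
    for key in ("image_size", "lesion_radius_px", "nucleus_radius_px",
                "typical_diameter_px", "white_reference"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    kwargs.update(overrides)
    return cls(**kwargs)


def burden_config(config: dict) -> BurdenConfig:
    section = dict(config.get("burden", {}))
    overrides = {}
    if "stain_basis" in section:
        basis = section.pop("stain_basis")
        if not isinstance(basis, dict):
            raise ConfigError("burden.stain_basis: must map stain name -> 3 numbers")
        overrides["stain_basis"] = StainBasis(list(basis.items()))
    return _build(BurdenConfig, section, "burden", **overrides)


def channel_configs(config: dict) -> dict[str, ChannelConfig]:
    section = config.get("coloc", {})
    out = dict(DEFAULT_CHANNEL_CONFIGS)
    for role, sub in section.items():
        if role not in out:
            raise ConfigError(f"coloc.{role}: unknown channel role")
        out[role] = _build(ChannelConfig, dict(sub), f"coloc.{role}", role=role)
    return out


def he_params(config: dict, seed: int) -> SynthHEParams:
    section = dict(config.get("simulate", {}).get("he", {}))
    section.pop("seed", None)
    section.pop("stain_basis", None)
    return _build(SynthHEParams, section, "simulate.he", seed=seed)


def fluor_params(config: dict, seed: int) -> SynthFluorParams:
    section = dict(config.get("simulate", {}).get("fluor", {}))
    section.pop("seed", None)
    return _build(SynthFluorParams, section, "simulate.fluor", seed=seed)


def defaults_as_dict() -> dict:
    """All configurable defaults, printable by ``lesionquant config show``."""
    b = BurdenConfig()
    return {
        "burden": {
            "stain_basis": {n: list(v) for n, v in b.stain_basis.stains},
            "tumor_channel": b.tumor_channel,
            "normal_channel": b.normal_channel,
            "smoothing_sigma_px": b.smoothing_sigma_px,
            "min_object_diameter_px": b.min_object_diameter_px,
            "white_reference": list(b.white_reference),
            "connectivity": b.connectivity,
            "n_bins": b.n_bins,
            "percent_of_total": b.percent_of_total,
        },
        "coloc": {
            role: {
                "typical_diameter_px": list(c.typical_diameter_px),
                "smoothing_sigma_px": c.smoothing_sigma_px,
                "discard_border": c.discard_border,
                "connectivity": c.connectivity,
                "n_bins": c.n_bins,
            }
            for role, c in DEFAULT_CHANNEL_CONFIGS.items()
        },
        "simulate": {
            "he": {
                f.name: (list(v) if isinstance((v := getattr(SynthHEParams(), f.name)), tuple) else v)
                for f in dataclasses.fields(SynthHEParams)
                if f.name not in ("stain_basis",)
            },
            "fluor": {
                f.name: (list(v) if isinstance((v := getattr(SynthFluorParams(), f.name)), tuple) else v)
                for f in dataclasses.fields(SynthFluorParams)
            },
        },
    }
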