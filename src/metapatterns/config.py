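"""YAML run configuration.

A config file fully determines a run: sampling ranges for the local
model, dispersal magnitude scales, the kappa grid and tolerances, and
equilibrium-search settings.  Every section is optional; omitted keys
fall back to package defaults.

Example::

    local:
      r: [0.5, 2.0]
      e: [0.1, 1.0]
    dispersal:
      diag_scale: 1.0
      off_scale: 1.0
    stability:
      kappa_min: 1.0e-3
      kappa_max: 1.0e+3
      n_kappa: 400
      zero_tol: 1.0e-9
      asymptotic_tol: 1.0e-9
    equilibrium:
      n_starts: 8
      seed: 0
"""

from __future__ import annotations

from dataclasses import fields
from typing import Any, Mapping

import numpy as np
import yaml

from .dispersal import DispersalConfig
from .motifs import DEFAULT_SAMPLING_RANGES, EquilibriumConfig
from .stability import StabilityConfig

__all__ = [
    "load_config",
    "sampling_ranges_from",
    "dispersal_config_from",
    "stability_config_from",
    "equilibrium_config_from",
]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def sampling_ranges_from(cfg: Mapping[str, Any]) -> dict[str, tuple[float, float]]:
    section = cfg.get("local", {})
    ranges = dict(DEFAULT_SAMPLING_RANGES)
    for key, bounds in section.items():
        if key not in ranges:
            raise ValueError(f"unknown local parameter class {key!r}")
        lo, hi = (float(b) for b in bounds)
        ranges[key] = (lo, hi)
    return ranges


def _from_section(cls, section: Mapping[str, Any]):
    names = {f.name for f in fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**section)


def dispersal_config_from(cfg: Mapping[str, Any]) -> DispersalConfig:
    return _from_section(DispersalConfig, cfg.get("dispersal", {}))


def stability_config_from(cfg: Mapping[str, Any]) -> StabilityConfig:
    section = dict(cfg.get("stability", {}))
    kmin = section.pop("kappa_min", 1e-3)
    kmax = section.pop("kappa_max", 1e3)
    nk = section.pop("n_kappa", 400)
    grid = np.concatenate(([0.0], np.logspace(np.log10(kmin), np.log10(kmax), nk)))
    return _from_section(StabilityConfig, {"kappa_grid": grid, **section})


def equilibrium_config_from(cfg: Mapping[str, Any]) -> EquilibriumConfig:
    return _from_section(EquilibriumConfig, cfg.get("equilibrium", {}))
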