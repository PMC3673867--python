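"""YAML/JSON configuration files mirroring GrowthDefaults and ModeConfig.

Example::

    mode:
      mode: MIXED
      coi_met: 3000
      coi_det: 3000
    growth:
      acetate_uptake_max: 18
      ngam_atp: 0.45
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import yaml

from voltflux.errors import ConfigurationError
from voltflux.mfc_modes import ModeConfig
from voltflux.model_core import GrowthDefaults


def load_config(path: str | Path) -> Tuple[GrowthDefaults, ModeConfig]:
    """Read a YAML (or JSON — a YAML subset) config file.

    Both sections are optional; omitted fields take the documented defaults.
    Unknown keys are rejected to catch typos early.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"growth", "mode"}
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")
    try:
        growth = GrowthDefaults(**(data.get("growth") or {}))
        mode = ModeConfig(**(data.get("mode") or {}))
    except TypeError as exc:
        raise ConfigurationError(f"bad config field: {exc}") from exc
    if isinstance(growth.free_exchange_ids, list):
        growth.free_exchange_ids = tuple(growth.free_exchange_ids)
    return growth, mode
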