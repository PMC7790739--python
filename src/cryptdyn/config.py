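"""Configuration serialisation: nested key/value text (YAML) <-> dataclasses."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .cell_cycle import CycleParams
from .engine import EngineConfig
from .mechanics import CryptDomain, MechParams
from .signalling import SignallingParams
from .wnt_field import WntConfig

__all__ = ["config_to_dict", "config_from_dict", "load_config",
           "save_config"]

_SECTIONS = {
    "domain": CryptDomain,
    "mech": MechParams,
    "wnt": WntConfig,
    "cycle": CycleParams,
    "signalling": SignallingParams,
}


def config_to_dict(cfg: EngineConfig) -> dict:
    out = {}
    for f in fields(EngineConfig):
        val = getattr(cfg, f.name)
        if f.name in _SECTIONS:
            sub = asdict(val)
            if f.name == "wnt":
                sub["mode"] = val.mode.value
            out[f.name] = sub
        else:
            out[f.name] = val
    return out


def config_from_dict(d: dict) -> EngineConfig:
    kwargs = {}
    for key, val in d.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](**val)
        else:
            kwargs[key] = val
    return EngineConfig(**kwargs)


def save_config(cfg: EngineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg),
                                         sort_keys=False))


def load_config(path: str | Path) -> EngineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
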