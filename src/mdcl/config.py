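"""YAML (de)serialization of the package's dataclass configurations."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .models import Net2DConfig, Net3DConfig
from .phantom import PhantomSpec
from .training import TrainConfig

__all__ = ["load_config", "save_config", "CONFIG_KINDS"]

CONFIG_KINDS = {
    "train": TrainConfig,
    "phantom": PhantomSpec,
    "net2d": Net2DConfig,
    "net3d": Net3DConfig,
}

_TUPLE_FIELDS = {"grid_size", "tube_radius_range", "fg_fraction_range", "window",
                 "stride", "input_size", "depths", "n_heads"}


def save_config(cfg, path) -> None:
    kind = next(k for k, cls in CONFIG_KINDS.items() if isinstance(cfg, cls))
    Path(path).write_text(yaml.safe_dump({"kind": kind, **asdict(cfg)}))


def load_config(path, kind: str | None = None):
    raw = yaml.safe_load(Path(path).read_text())
    kind = kind or raw.pop("kind", None)
    if kind not in CONFIG_KINDS:
        raise ValueError(f"config kind must be one of {sorted(CONFIG_KINDS)}, got {kind!r}")
    raw.pop("kind", None)
    cls = CONFIG_KINDS[kind]
    valid = {f.name for f in fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown {kind} config keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in raw.items()
    }
    return cls(**coerced)
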