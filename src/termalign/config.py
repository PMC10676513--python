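"""Run configuration: YAML loading, defaults, overrides, and hashing."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .termbase import TermbaseError

__all__ = ["DEFAULTS", "load_config", "merge", "config_hash", "set_by_path"]

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "encoder": {"backend": "test", "dim": 768, "max_tokens": 128},
    "projection": {"dim": 300},
    "gat": {"heads": 2, "layers": 2, "leaky_slope": 0.2},
    "neighbors": {"cap": 25},
    "path": {"n": 5, "k": 2, "max_paths": 4},
    "kernels": {"count": 10, "exact_sigma": 0.001, "sigma": 0.1},
    "fusion": {"hidden": 64},
    "ablation": {
        "views": ["semantic", "neighborhood", "path"],
        "use_gates": True,
        "path_pooling": "kernel",
        "aggregator": "gat",
    },
    "training": {
        "margin": 1.0,
        "negatives_per_positive": 5,
        "candidate_pool": 50,
        "epochs": 20,
        "learning_rate": 0.01,
        "train_fraction": 0.3,
        "seed_cap": 15000,
    },
    "synth": {
        "n_concepts": 200,
        "max_depth": 4,
        "branching": [2, 4],
        "p_reassign": 0.0,
        "p_insert": 0.0,
        "p_synonym": 0.0,
    },
    "sweep": {"fractions": [0.05, 0.1, 0.2, 0.5, 0.7, 1.0]},
}


def merge(base: Mapping, override: Mapping) -> dict:
    """Recursive dict merge; override wins, unknown keys rejected."""
    out = copy.deepcopy(dict(base))
    for key, val in override.items():
        if key not in out:
            raise TermbaseError(f"unknown config key {key!r}")
        if isinstance(out[key], dict):
            if not isinstance(val, Mapping):
                raise TermbaseError(f"config key {key!r} expects a mapping")
            out[key] = merge(out[key], val)
        else:
            out[key] = val
    return out


def set_by_path(cfg: dict, dotted: str, value: Any) -> None:
    """Set ``cfg['a']['b'] = value`` from a dotted path ``a.b`` (in place)."""
    keys = dotted.split(".")
    node = cfg
    for k in keys[:-1]:
        if k not in node or not isinstance(node[k], dict):
            raise TermbaseError(f"unknown config path {dotted!r} (at {k!r})")
        node = node[k]
    if keys[-1] not in node:
        raise TermbaseError(f"unknown config path {dotted!r}")
    old = node[keys[-1]]
    if old is not None and not isinstance(old, (dict, list)) and not isinstance(value, type(old)):
        try:
            value = type(old)(value)
        except (TypeError, ValueError):
            raise TermbaseError(f"config path {dotted!r}: cannot coerce {value!r}")
    node[keys[-1]] = value


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file and explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = merge(cfg, doc)
    if overrides:
        cfg = merge(cfg, overrides)
    return cfg


def config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
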