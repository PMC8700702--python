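"""Run configuration: defaults, YAML loading, canonical hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    """All pipeline defaults in one place.

    Unknown keys in a config file are rejected so typos cannot silently
    fall back to defaults; the canonical hash of the config is stamped
    into every output for provenance.
    """

    # embedding
    p: int = 3
    lag: int = 1
    keep_space: bool = True
    # recurrence
    lmin: int = 2
    theiler_w: int = 1
    target_rr: float = 0.05
    radius: float | None = None  # fixed radius overrides target_rr
    # windowing
    window_symbols: int = 300
    step_symbols: int = 300
    window_seconds: float = 60.0
    step_seconds: float = 60.0
    resample_hz: float = 4.0
    max_gap_s: float = 2.0
    # state dynamics
    k: int | str = "auto"  # "auto" -> silhouette-selected over 2..8
    n_init: int = 10
    features: tuple = ("RR", "DET")
    smoothing: float = 0.0
    # shared component
    loading_floor: float = 0.3
    symbol_bins: int = 3
    # misc
    seed: int = 20211125

    def to_canonical_json(self) -> str:
        d = asdict(self)
        d["features"] = list(d["features"])
        return json.dumps(d, sort_keys=True, separators=(",", ":"))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.to_canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (single top-level mapping); reject unknown keys."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a single top-level mapping")
        data.update(raw)
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "features" in data:
        data["features"] = tuple(data["features"])
    return RunConfig(**data)
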