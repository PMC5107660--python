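"""Configuration loading, run provenance, and tabular output writers."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .rulesets import RuleSet, hypothesis1, hypothesis2
from .simulator import SimConfig, Trajectory

__all__ = [
    "CONFIG_DEFAULTS",
    "load_config",
    "save_config",
    "build_sim_config",
    "build_rules",
    "RunManifest",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

# Flat configuration schema.  Engine keys mirror SimConfig; rule keys override
# scalar parameters of the chosen hypothesis; image keys mirror the detection
# pipeline defaults.
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_RULE_KEYS = {"hypothesis", "N_crit", "c_envfactor", "c_amount", "max_target_neighbors"}
_IMAGE_KEYS = {"threshold", "mask_threshold", "mask_min_size", "nucleus_max_size"}

CONFIG_DEFAULTS: dict = {
    # engine
    "grid_size": 32,
    "n_cells": 30_000,
    "engraft_prob": None,
    "n_steps": 80,
    "record_every": 10,
    "seeding_mode": "instant_cull",
    "substrate_deposit_mode": "once",
    "slice_axis": "z",
    "n_slices": 30,
    "record_cvhv": True,
    "engine": "fast",
    "c_formula_scale": 20.0,
    "c_formula_divisor": 21.2,
    # rules
    "hypothesis": 1,
    "N_crit": 5.0,
    "c_envfactor": 1.9,
    "c_amount": 1.0,
    "max_target_neighbors": 6,
    # image pipeline
    "threshold": 125,
    "mask_threshold": 85,
    "mask_min_size": 300,
    "nucleus_max_size": 20,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file, fill defaults, reject unknown keys.

    An empty (or absent) file yields the pure default configuration.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a mapping")
        user = loaded
    unknown = sorted(set(user) - set(CONFIG_DEFAULTS))
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
    cfg = dict(CONFIG_DEFAULTS)
    cfg.update(user)
    if cfg["hypothesis"] not in (1, 2):
        raise ValueError("hypothesis must be 1 or 2")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def build_sim_config(cfg: dict) -> SimConfig:
    return SimConfig(**{k: cfg[k] for k in _SIM_KEYS})


def build_rules(cfg: dict) -> RuleSet:
    base = hypothesis1() if cfg["hypothesis"] == 1 else hypothesis2()
    overrides = {
        k: cfg[k] for k in ("N_crit", "c_envfactor", "c_amount", "max_target_neighbors")
        if cfg[k] != getattr(base, k)
    }
    return base.replace(**overrides) if overrides else base


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    config: dict
    seed: int
    software_version: str = ""
    created: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    outputs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__

            self.software_version = __version__

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["config_hash"] = self.config_hash
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        data.pop("config_hash", None)
        return cls(**data)


def write_trajectory_csv(
    trajectory: Trajectory | pd.DataFrame, path: str | Path, replicate: int = 0
) -> Path:
    """Write a trajectory (or a long-format replicate table) as CSV.

    Columns: replicate, time_step, slice_index, n_cells, cvhv.
    """
    df = trajectory.to_frame(replicate) if isinstance(trajectory, Trajectory) else trajectory
    if df.empty:
        raise ValueError("refusing to write an empty trajectory")
    expected = ["replicate", "time_step", "slice_index", "n_cells", "cvhv"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table lacks columns: {missing}")
    path = Path(path)
    df[expected].to_csv(path, index=False)
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["replicate", "time_step", "slice_index", "n_cells", "cvhv"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory CSV lacks columns: {missing}")
    return df
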