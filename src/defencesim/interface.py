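"""Configuration loading, deterministic seeding, and result/manifest I/O.

Config files are YAML. A single global seed expands to per-run seeds via a
counter-based scheme (:func:`derive_run_seed`), so any treatment cell and
replicate can be re-run independently yet bit-identically. Results are tidy
CSVs with a deterministic row order plus a JSON manifest that inventories
every written file with a checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .params import SimParams

__all__ = [
    "ConfigError",
    "RunManifest",
    "derive_run_seed",
    "load_config",
    "config_to_dict",
    "write_config",
    "write_results",
]

PRESETS = ("control", "costs_i", "benefits_ii", "net_iii")


class ConfigError(ValueError):
    """Raised for unknown keys or out-of-range values in a config file."""


@dataclass(frozen=True)
class RunManifest:
    """Inventory of one output bundle; sufficient to re-run bit-identically."""

    version: str
    config: dict
    seeds: list[int]
    files: dict[str, dict]   # filename -> {sha256, bytes, rows}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_run_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-run seed from (base seed, cell counter, replicate).

    Uses numpy's SeedSequence spawn-key mechanism and folds the result below
    2**31 so the seed is portable as a signed 32-bit integer.
    """
    ss = np.random.SeedSequence(int(base_seed), spawn_key=(int(cell_index), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def _scenario_fields() -> dict:
    from .scenarios import ScenarioConfig

    return {f.name: f for f in dataclasses.fields(ScenarioConfig)}


def config_to_dict(cfg) -> dict:
    """Flatten a ScenarioConfig (with nested SimParams) to plain data."""
    out = dataclasses.asdict(cfg)
    out["params"] = cfg.params.to_dict()
    return out


def load_config(path: str | Path) -> "ScenarioConfig":
    """Load and validate a YAML scenario config; defaults fill missing keys.

    Recognised top-level keys are the ScenarioConfig fields plus ``preset``
    (control / costs_i / benefits_ii / net_iii) and a nested ``params``
    mapping of SimParams overrides. Unknown keys raise a ConfigError naming
    the offenders.
    """
    from .scenarios import ScenarioConfig

    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    field_names = set(_scenario_fields())
    allowed = field_names | {"preset"}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")

    kwargs = {k: v for k, v in raw.items() if k in field_names and k != "params"}
    preset = raw.get("preset", "control")
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    if preset != "control":
        kwargs.setdefault("suite", preset)

    params_raw = raw.get("params", {}) or {}
    if not isinstance(params_raw, dict):
        raise ConfigError("params must be a mapping")
    sim_fields = {f.name for f in dataclasses.fields(SimParams)}
    bad = sorted(set(params_raw) - sim_fields)
    if bad:
        raise ConfigError(f"unknown params keys: {bad}")
    try:
        kwargs["params"] = SimParams(**params_raw)
        return ScenarioConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def write_config(cfg, path: str | Path) -> None:
    """Serialise a ScenarioConfig to YAML (round-trips through load_config)."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True), encoding="utf-8"
    )


def _sort_frame(df: pd.DataFrame) -> pd.DataFrame:
    preferred = [c for c in ("cell_id", "c", "h", "d", "D", "replicate", "plant_id") if c in df.columns]
    keys = preferred or list(df.columns)
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def write_results(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seeds: list[int] | None = None,
) -> RunManifest:
    """Write result tables as CSV plus a JSON manifest; fully deterministic.

    ``results`` maps a table name (e.g. ``yields``) to a DataFrame. Rows are
    sorted deterministically and files written UTF-8 with ``\\n`` endings, so
    writing the same results twice is byte-identical. Empty input raises
    before anything is written.
    """
    from . import __version__

    if not results or all(df.empty for df in results.values()):
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    inventory: dict[str, dict] = {}
    for name, df in results.items():
        fname = f"{name}.csv"
        payload = _sort_frame(df).to_csv(index=False, lineterminator="\n").encode("utf-8")
        (out / fname).write_bytes(payload)
        inventory[fname] = {
            "sha256": hashlib.sha256(payload).hexdigest(),
            "bytes": len(payload),
            "rows": int(len(df)),
        }

    manifest = RunManifest(
        version=__version__,
        config=config or {},
        seeds=sorted(set(seeds or [])),
        files=inventory,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
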