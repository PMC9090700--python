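"""Tidy trial-table I/O: CSV with a YAML sidecar for simulation metadata."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimConfig, TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "load_config"]


def write_trials(trials: pd.DataFrame, path, config: SimConfig | None = None) -> None:
    """Write a tidy trial CSV; if a SimConfig is given, also write a
    ``<stem>.yaml`` sidecar with the full configuration (seed included)."""
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    extra = [c for c in trials.columns if c not in cols]
    trials[cols + extra].to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(".yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump({"sim_config": config.to_dict()}, fh, sort_keys=False)


def read_trials(path) -> pd.DataFrame:
    """Read a tidy trial CSV, coercing the boolean correctness flags."""
    df = pd.read_csv(path)
    for col in ("correct1", "correct2"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def load_config(path) -> SimConfig:
    """Load a SimConfig from a YAML file (either bare or under 'sim_config')."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "sim_config" in data:
        data = data["sim_config"]
    field_names = {f.name for f in dataclasses.fields(SimConfig)}
    kwargs = {k: v for k, v in data.items() if k in field_names}
    if "memory_params" in kwargs and isinstance(kwargs["memory_params"], dict):
        from .simulate import MemoryModelParams

        kwargs["memory_params"] = MemoryModelParams(**kwargs["memory_params"])
    if "soa_levels" in kwargs:
        kwargs["soa_levels"] = tuple(kwargs["soa_levels"])
    return SimConfig(**kwargs)
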