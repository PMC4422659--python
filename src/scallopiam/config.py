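"""YAML configuration parsing and result serialization.

Configs are flat YAML mappings of :class:`~scallopiam.simulator.ScenarioConfig`
fields, with parameter overrides under ``params`` as dotted paths
(``scallop.GB.K: 0.5``). Unknown keys are rejected by name. Results are
written as tidy CSV (one row per run and year) plus a JSON metadata sidecar
sufficient to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .simulator import ResultSet, ScenarioConfig

__all__ = ["parse_config", "write_results", "read_results"]

_CFG_FIELDS = {f.name for f in dataclasses.fields(ScenarioConfig)}


class ConfigError(ValueError):
    """Raised for schema violations in user configuration."""


def parse_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario configuration, defaults overlaid with user values."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(raw).__name__}")
    params = raw.pop("params", {}) or {}
    if not isinstance(params, dict):
        raise ConfigError(f"{path}: 'params' must be a mapping of dotted paths")
    unknown = set(raw) - _CFG_FIELDS
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_CFG_FIELDS)}")
    for key, val in raw.items():
        want = next(f for f in dataclasses.fields(ScenarioConfig) if f.name == key)
        if want.type in ("int", "float") and not isinstance(val, (int, float)):
            raise ConfigError(f"{path}: key {key!r} expects {want.type}, "
                              f"got {type(val).__name__}")
    try:
        return ScenarioConfig(**raw, param_overrides=dict(params))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_results(rs: ResultSet, out_dir: str | Path) -> dict:
    """Write a ResultSet as CSVs + metadata JSON; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if rs.runs:
        allruns = pd.concat(rs.runs, keys=range(len(rs.runs)),
                            names=["run", "row"]).reset_index("run").reset_index(drop=True)
        paths["runs"] = out / "runs.csv"
        allruns.to_csv(paths["runs"], index=False)
    if not rs.aggregate.empty:
        paths["aggregate"] = out / "aggregate.csv"
        rs.aggregate.to_csv(paths["aggregate"], index=False)
    meta = dict(rs.metadata)
    meta["failures"] = rs.failures
    paths["metadata"] = out / "metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, default=str))
    return paths


def read_results(out_dir: str | Path) -> ResultSet:
    """Re-read a result directory written by :func:`write_results`."""
    out = Path(out_dir)
    meta = json.loads((out / "metadata.json").read_text())
    failures = meta.pop("failures", [])
    runs = []
    runs_path = out / "runs.csv"
    if runs_path.exists():
        allruns = pd.read_csv(runs_path)
        runs = [g.drop(columns="run").reset_index(drop=True)
                for _, g in allruns.groupby("run")]
    agg_path = out / "aggregate.csv"
    aggregate = pd.read_csv(agg_path) if agg_path.exists() else pd.DataFrame()
    return ResultSet(runs=runs, aggregate=aggregate, metadata=meta,
                     failures=failures)
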