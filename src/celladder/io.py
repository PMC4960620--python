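"""Readers/writers for cycle tables, distribution tables and configs.

Cycle tables are plain CSV (comma separator, '.' decimal, UTF-8, header
row, no quoting of numerics) preceded by '#'-commented provenance lines
that embed the fully resolved configuration and seed as JSON.  Floats
are written with ``repr`` (shortest round-trip form), so read-then-write
reproduces the file byte for byte.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import BurstLaw, ConfigError, MechanismSpec, ModelParams

__all__ = [
    "write_cycles",
    "read_cycles",
    "write_distribution_table",
    "read_distribution_table",
    "load_config",
    "resolve_config",
    "build_model_params",
    "build_mechanism",
    "DEFAULT_CONFIG",
]

# Canonical study conditions: transcription rate 0.13 /min (concentration
# sense), growth rate 0.03 /min, threshold 65 molecules, geometric bursts
# with mean 5 — the parameter set used throughout for model predictions.
DEFAULT_CONFIG: dict = {
    "k_m": 0.13,
    "alpha": 0.03,
    "X": 65,
    "V_b": 3.0,
    "burst": {"kind": "geometric", "mean_b": 5.0, "support_start": 1},
    "mechanism": {"kind": "baseline"},
    "n": 10_000,
    "seed": 0,
    "n_max": None,
}


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return str(x)


def write_cycles(df: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write a cycle table as commented-header CSV."""
    path = Path(path)
    lines = []
    if config is not None:
        lines.append("# config: " + json.dumps(config, sort_keys=True))
    lines.append(",".join(df.columns))
    for row in df.itertuples(index=False):
        lines.append(",".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_cycles(path) -> tuple[pd.DataFrame, dict | None]:
    """Read a cycle table; returns (frame, embedded config or None)."""
    path = Path(path)
    config = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# config:"):
                config = json.loads(line[len("# config:"):])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return df, config


def write_distribution_table(path, x, density, name: str, config: dict | None = None) -> None:
    """Two-column (value, density) tab-delimited table with a commented
    header naming the distribution and the generating parameters."""
    path = Path(path)
    lines = [f"# distribution: {name}"]
    if config is not None:
        lines.append("# config: " + json.dumps(config, sort_keys=True))
    lines.append("value\tdensity")
    for xi, fi in zip(np.asarray(x), np.asarray(density)):
        lines.append(f"{_fmt(xi)}\t{_fmt(fi)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_distribution_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
def load_config(path) -> dict:
    """Load a YAML/JSON config file and resolve it against the defaults."""
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config file must contain a mapping")
    return resolve_config(user)


def resolve_config(user: dict | None) -> dict:
    """Merge a partial config over the defaults (one level of nesting)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def build_burst(cfg: dict) -> BurstLaw:
    b = cfg["burst"]
    kind = b.get("kind", "geometric")
    if kind == "geometric":
        return BurstLaw.geometric(float(b["mean_b"]), support_start=int(b.get("support_start", 1)))
    if kind == "deterministic":
        return BurstLaw.deterministic(int(b["value"]))
    if kind == "tabulated":
        return BurstLaw.tabulated(tuple((int(k), float(p)) for k, p in b["pmf"]))
    raise ConfigError(f"unknown burst kind {kind!r}")


def build_model_params(cfg: dict) -> ModelParams:
    return ModelParams(
        k_m=float(cfg["k_m"]),
        alpha=float(cfg["alpha"]),
        burst=build_burst(cfg),
        X=int(cfg["X"]),
        V_b=float(cfg["V_b"]),
    )


def build_mechanism(cfg: dict) -> MechanismSpec:
    m = dict(cfg.get("mechanism") or {"kind": "baseline"})
    kind = m.pop("kind", "baseline")
    fields = {k: (float(v) if v is not None else None) for k, v in m.items()}
    return MechanismSpec(kind=kind, **fields)
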