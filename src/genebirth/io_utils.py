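"""Configuration loading, seed derivation, and result serialization.

Seeds are derived through ``numpy.random.SeedSequence`` spawn keys: the
stream for replicate r of grid entry i at deletion index j under regime
g is ``SeedSequence(seed_base, spawn_key=(g, i, j, r))``, so any subset
of a sweep reproduces the full sweep's replicates bit-for-bit.  Tables
are written as CSV at full double precision, summaries and run
manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dfe import DFEParams
from .population import SimConfig

__all__ = [
    "derive_rng",
    "load_config",
    "write_results",
    "make_manifest",
]


def derive_rng(seed_base: int, *key: int) -> np.random.Generator:
    """Independent generator for a hierarchical key under a base seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed_base), spawn_key=tuple(int(k) for k in key))
    )


_DFE_KEYS = {"p", "f", "n", "s"}


def load_config(
    path: str | Path | None = None, **overrides
) -> tuple[SimConfig, DFEParams | None]:
    """Build a validated configuration from a YAML file and/or overrides.

    The file is a flat mapping of ``SimConfig`` fields plus optional DFE
    parameters p, f, n, s; keyword overrides (e.g. CLI flags) take
    precedence.  Defaults are the standard model values (T=1000,
    fitness threshold 0.1, E0=1e-3, alpha=2.25, neutral threshold 5e-4).
    Unknown keys raise a validation error naming the key.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a flat mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})

    dfe_values = {k: values.pop(k) for k in list(values) if k in _DFE_KEYS}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    config = SimConfig(**values)

    dfe = None
    if dfe_values:
        missing = _DFE_KEYS - set(dfe_values)
        if missing:
            raise ValueError(f"incomplete DFE specification, missing {sorted(missing)}")
        dfe = DFEParams(**dfe_values)
    return config, dfe


def make_manifest(
    config: SimConfig,
    seed_base: int,
    dfe: DFEParams | None = None,
    **extra,
) -> dict:
    """Run manifest: full configuration echo plus seed and version info."""
    from . import __version__

    manifest = {
        "config": dataclasses.asdict(config),
        "dfe": dataclasses.asdict(dfe) if dfe is not None else None,
        "seed_base": int(seed_base),
        "seeding": "SeedSequence(seed_base, spawn_key=(regime, dfe_index, d_index, replicate))",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    manifest.update(extra)
    return manifest


def write_results(
    out_dir: str | Path,
    tables: dict[str, pd.DataFrame] | None = None,
    summaries: dict[str, dict] | None = None,
    manifest: dict | None = None,
) -> list[Path]:
    """Write result tables (CSV), summaries (JSON) and the manifest.

    Column order is whatever the tables carry; re-running with identical
    inputs rewrites identical files (timestamps live only in the
    manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in (tables or {}).items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    for name, summary in (summaries or {}).items():
        path = out / f"{name}.json"
        path.write_text(json.dumps(summary, indent=2, default=_jsonify) + "\n")
        written.append(path)
    if manifest is not None:
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=_jsonify) + "\n")
        written.append(path)
    return written


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
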