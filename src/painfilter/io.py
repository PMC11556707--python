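"""Configuration parsing, run manifests, and table readers/writers.

Scenario configs are flat key-value YAML files; outputs are comma-separated
tables (12 significant digits, '.' decimal, UTF-8) plus a JSON manifest
recording the seed and the full effective parameter snapshot so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .params import ConfigurationError, SchemaError
from .scenarios import AggregateResult, ScenarioConfig

__all__ = [
    "RunManifest",
    "parse_config",
    "write_outputs",
    "load_rating_table",
]

_TOP_LEVEL_KEYS = {"scenario", "model", "seed", "n_replicates", "n_individuals"}


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: scenario, seed and the full
    effective parameter snapshot.  The hash covers exactly those fields, so
    it changes iff an effective parameter changes."""

    scenario: str
    seed: int
    parameters: dict
    version: str = __version__
    timestamp: Optional[str] = None

    @classmethod
    def for_config(cls, config: ScenarioConfig, stamp: bool = False) -> "RunManifest":
        import inspect

        from .scenarios import SCENARIOS

        fn = SCENARIOS[config.name]
        snapshot = {
            name: p.default
            for name, p in inspect.signature(fn).parameters.items()
            if name != "seed"
        }
        snapshot.update(config.overrides)
        if config.n_replicates is not None and "n_replicates" in snapshot:
            snapshot["n_replicates"] = config.n_replicates
        if config.n_individuals is not None and "n_individuals" in snapshot:
            snapshot["n_individuals"] = config.n_individuals
        ts = datetime.now(timezone.utc).isoformat() if stamp else None
        return cls(
            scenario=config.name, seed=config.seed, parameters=snapshot, timestamp=ts
        )

    def canonical(self) -> str:
        payload = {
            "scenario": self.scenario,
            "seed": self.seed,
            "parameters": self.parameters,
        }
        return json.dumps(payload, sort_keys=True, default=repr)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode("utf-8")).hexdigest()

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "seed": self.seed,
            "parameters": {k: repr(v) if isinstance(v, (dict, tuple)) else v
                           for k, v in self.parameters.items()},
            "version": self.version,
            "config_hash": self.config_hash,
        }
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d


def parse_config(path) -> ScenarioConfig:
    """Read and validate a flat YAML scenario config.

    Unknown keys raise a named validation error; out-of-range values (e.g.
    a non-positive variance) raise a range error.  Every omitted key takes
    its documented default.
    """
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a flat key-value mapping")
    name = raw.pop("scenario", None)
    if name is None:
        raise ConfigurationError(f"config {path} is missing the 'scenario' key")
    model = raw.pop("model", None)
    seed = int(raw.pop("seed", 0))
    n_replicates = raw.pop("n_replicates", None)
    n_individuals = raw.pop("n_individuals", None)
    overrides = dict(raw)  # every remaining key is a scenario override
    return ScenarioConfig(
        name=name,
        model=model,
        seed=seed,
        n_replicates=None if n_replicates is None else int(n_replicates),
        n_individuals=None if n_individuals is None else int(n_individuals),
        overrides=overrides,
    )


def write_outputs(result: AggregateResult, manifest: RunManifest, outdir) -> dict:
    """Write trajectory/summary tables and the manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if result.trajectories is not None:
        p = outdir / f"{result.name}_trajectories.csv"
        result.trajectories.to_csv(p, index=False, float_format="%.12g")
        paths["trajectories"] = p
    if result.cells is not None:
        p = outdir / f"{result.name}_summary.csv"
        result.cells.to_csv(p, index=False, float_format="%.12g")
        paths["summary"] = p
    p = outdir / f"{result.name}_manifest.json"
    p.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True), encoding="utf-8")
    paths["manifest"] = p
    return paths


_RATING_COLUMNS = [
    "individual",
    "trial",
    "cue",
    "temperature",
    "expected_rating",
    "pain_rating",
]


def load_rating_table(path, sep: str = ",") -> pd.DataFrame:
    """Optional loader for trial-level human rating tables (100-unit VAS).

    Only used for side-by-side comparison plots; nothing in the simulator or
    its tests depends on external data.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _RATING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"rating table {path} is missing column(s): {', '.join(missing)}")
    for col in ("expected_rating", "pain_rating"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if ((vals < 0) | (vals > 100)).any():
            warnings.warn(
                f"{col} contains values outside the 100-unit rating scale",
                stacklevel=2,
            )
    return df
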