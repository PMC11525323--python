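"""YAML/JSON run configuration and the run manifest.

One configuration file drives the pipeline: a ``simulate`` block (study
conditions for the synthetic-data generator), a ``model`` block (which of
the four numbered models, or explicit family flags), a ``priors`` block,
and an ``mcmc`` block.  Field names mirror the corresponding dataclasses
one-to-one.  Every output directory gets exactly one ``manifest.json``
recording the configuration snapshot, seeds, package version, and input
file digests, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .mcmc import MCMCConfig
from .models import ModelSpec, PriorConfig, model_number_spec
from .simulate import SimConfig

__all__ = ["RunConfig", "RunManifest", "load_config", "write_manifest"]


class ConfigError(ValueError):
    """Configuration schema violation (raised before any compute)."""


def _take(block: dict, cls, what: str):
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"invalid {what} block: {exc}") from exc


@dataclass
class RunConfig:
    """Parsed configuration for simulate / fit / recover runs."""

    simulate: SimConfig = field(default_factory=SimConfig)
    model: int = 3
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    recover: dict[str, Any] = field(default_factory=dict)

    def model_spec(self) -> ModelSpec:
        return model_number_spec(self.model, self.priors)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON) config file into a validated RunConfig."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"simulate", "model", "priors", "mcmc", "recover"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    sim_block = dict(raw.get("simulate", {}))
    if "beta" in sim_block:
        sim_block["beta"] = np.asarray(sim_block["beta"], dtype=float)
    if "alpha" in sim_block:
        sim_block["alpha"] = tuple(sim_block["alpha"])
    model = raw.get("model", 3)
    if isinstance(model, dict):
        model = model.get("number", 3)
    if model not in (1, 2, 3, 4):
        raise ConfigError(f"{path}: model must be 1..4, got {model!r}")
    try:
        return RunConfig(
            simulate=_take(sim_block, SimConfig, "simulate"),
            model=int(model),
            priors=_take(dict(raw.get("priors", {})), PriorConfig, "priors"),
            mcmc=_take(dict(raw.get("mcmc", {})), MCMCConfig, "mcmc"),
            recover=dict(raw.get("recover", {})),
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunManifest:
    """Reproducibility record written once per output directory."""

    command: str
    config: dict[str, Any]
    seeds: dict[str, int]
    version: str
    input_digests: dict[str, str]
    created: str


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict[str, Any],
    seeds: dict[str, int],
    inputs: dict[str, str | Path] | None = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config=_jsonable(config),
        seeds={k: int(v) for k, v in seeds.items()},
        version=__version__,
        input_digests={k: _digest(Path(p)) for k, p in (inputs or {}).items()},
        created=datetime.now(timezone.utc).isoformat(),
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")
    return path


def config_snapshot(cfg: RunConfig) -> dict[str, Any]:
    return _jsonable(
        {
            "simulate": asdict(cfg.simulate),
            "model": cfg.model,
            "priors": asdict(cfg.priors),
            "mcmc": asdict(cfg.mcmc),
            "recover": cfg.recover,
        }
    )
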