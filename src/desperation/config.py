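"""Run configuration: YAML schema, validation, and reproducibility manifest.

A run config is a flat YAML mapping. Keys mirror :class:`ModelParams` plus a
few run-control settings; unknown keys are rejected with their path so typos
surface before any computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "write_manifest"]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}

_RUN_FIELDS = {
    "experiment": str,
    "seed": int,
    "out_dir": str,
    "update_fraction": float,
    "tol": float,
    "window": int,
    "max_steps": int,
    "init": object,
    "rates": list,
    "v_values": list,
    "e_panels": list,
    "k_steps": int,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters plus run-control settings."""

    params: ModelParams = field(default_factory=ModelParams)
    experiment: str = "equilibrium"
    seed: int = 0
    out_dir: str = "results"
    update_fraction: float = 0.1
    tol: float = 1e-4
    window: int = 100
    max_steps: int = 1000
    init: object = "all_submissive"
    rates: tuple = (0.005, 0.01, 0.02, 0.03, 0.04)
    v_values: tuple = tuple(round(x, 3) for x in [0.02 * i for i in range(1, 48)])
    e_panels: tuple = (0.05, 0.3)
    k_steps: int = 10

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(raw) - _PARAM_FIELDS - set(_RUN_FIELDS)
        if unknown:
            raise ValueError(
                "unknown config keys: " + ", ".join(sorted(unknown))
            )
        param_kwargs = {k: raw[k] for k in raw if k in _PARAM_FIELDS}
        run_kwargs = {k: raw[k] for k in raw if k in _RUN_FIELDS}
        for key in ("rates", "v_values", "e_panels"):
            if key in run_kwargs:
                run_kwargs[key] = tuple(run_kwargs[key])
        try:
            params = ModelParams(**param_kwargs)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid model parameters: {exc}") from exc
        return cls(params=params, **run_kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self.params)
        for f in dataclasses.fields(self):
            if f.name == "params":
                continue
            value = getattr(self, f.name)
            out[f.name] = list(value) if isinstance(value, tuple) else value
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Omitted keys fall back to the typical-value defaults; schema violations
    and parameter-constraint violations (e.g. a profitable exploitation
    stake) are reported with the offending keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig) -> Path:
    """Write a reproducibility manifest (config hash, seed, version)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "package_version": __version__,
        "config": config.to_dict(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
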