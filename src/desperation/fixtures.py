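"""Deterministic small fixtures for tests and demos."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import RunConfig, save_config
from .params import ModelParams

__all__ = ["make_fixture"]


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> Path:
    """Write a small deterministic fixture and return its path.

    Kinds:

    * ``tiny_population`` — a 10-agent CSV (3 exploiters, 2 violent,
      5 submissive; 4 agents below the threshold) with seed-jittered but
      sign-stable resources.
    * ``policy_toy`` — a YAML config with a 5-point resource grid and a
      short horizon, sized for exhaustive-enumeration checks.
    * ``sweep_toy`` — a YAML config with 3 increasing desperation rates and
      a small population.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "tiny_population":
        path = out_dir / "tiny_population.csv"
        strategies = ["exploit"] * 3 + ["violent"] * 2 + ["submissive"] * 5
        signs = np.array([-1, -1, -1, -1, 1, 1, 1, 1, 1, 1], dtype=float)
        resources = signs * (1.0 + np.round(9.0 * rng.random(10), 3))
        lines = ["resources,strategy"]
        lines += [f"{x:.3f},{s}" for x, s in zip(resources, strategies)]
        path.write_text("\n".join(lines) + "\n")
        return path
    if kind == "policy_toy":
        path = out_dir / "policy_toy.yaml"
        cfg = RunConfig(
            params=ModelParams(
                mu=1.0, sigma=2.0, r=0.5, N_pop=10, n_targets=2,
                T=2, grid_lo=-2.0, grid_hi=2.0, grid_n=5,
            ),
            seed=seed,
        )
        save_config(cfg, path)
        return path
    if kind == "sweep_toy":
        path = out_dir / "sweep_toy.yaml"
        cfg = RunConfig(
            params=ModelParams(N_pop=500, grid_n=101),
            experiment="hysteresis",
            rates=(0.005, 0.02, 0.04),
            max_steps=300,
            seed=seed,
        )
        save_config(cfg, path)
        return path
    raise ValueError(f"unknown fixture kind {kind!r}")
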