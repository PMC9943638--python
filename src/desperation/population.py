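"""Agent-based population simulation.

A population of agents with Gaussian-distributed resources repeatedly
revises its strategies: each step, a randomly chosen fraction (10% by
default) of agents adopts the strategy that is optimal for their own
resource level given the current population strategy frequencies, which all
agents observe perfectly. Partial asynchronous updating lets the strategy
distribution move smoothly to an equilibrium instead of oscillating.

Resources are held fixed while strategies converge, so the desperation rate
(the fraction of agents below the threshold) is an exogenous property of the
initial Gaussian draw. Set ``dynamic_resources=True`` on
:func:`run_to_equilibrium` to let outcomes and AR(1) shocks move resources
instead (exploratory; off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import EXPLOIT, STRATEGIES, SUBMISSIVE, VIOLENT, ModelParams, StrategyFreqs
from .sdp import backward_induction

__all__ = [
    "Population",
    "EquilibriumResult",
    "init_population",
    "measure",
    "update_step",
    "run_to_equilibrium",
]

_CODE = {"submissive": SUBMISSIVE, "violent": VIOLENT, "exploit": EXPLOIT}


@dataclass(frozen=True)
class Population:
    """Agent resource levels and strategy codes (int8, see STRATEGIES)."""

    resources: np.ndarray
    strategies: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.resources) != len(self.strategies):
            raise ValueError("resources and strategies must have equal length")
        if len(self.resources) == 0:
            raise ValueError("empty population")
        if not np.isin(self.strategies, (SUBMISSIVE, VIOLENT, EXPLOIT)).all():
            raise ValueError("invalid strategy codes")

    def __len__(self) -> int:
        return len(self.resources)


@dataclass(frozen=True)
class EquilibriumResult:
    """Converged state of a strategy-revision run.

    ``trajectory`` holds one row per step with columns
    ``step, e, v, s, desperation_rate``.
    """

    final_freqs: StrategyFreqs
    desperation_rate: float
    trajectory: pd.DataFrame
    converged: bool
    steps: int


def init_population(params: ModelParams, seed: int | None, init) -> Population:
    """Draw a Gaussian population with a chosen initial strategy mix.

    ``init`` is ``"all_submissive"``, ``"all_violent"``, or a float ``p`` in
    [0, 1] meaning an exact fraction ``p`` of violent agents (remainder
    submissive), placed at random.
    """
    rng = np.random.default_rng(seed)
    n = params.N_pop
    resources = rng.normal(params.mu, params.sigma, size=n)
    strategies = np.empty(n, dtype=np.int8)
    if init == "all_submissive":
        strategies.fill(SUBMISSIVE)
    elif init == "all_violent":
        strategies.fill(VIOLENT)
    elif isinstance(init, (int, float)) and not isinstance(init, bool):
        p = float(init)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"violent fraction {p} must lie in [0, 1]")
        k = int(round(p * n))
        strategies.fill(SUBMISSIVE)
        strategies[rng.permutation(n)[:k]] = VIOLENT
    else:
        raise ValueError(f"unknown init {init!r}")
    return Population(resources=resources, strategies=strategies, rng_seed=seed)


def measure(pop: Population, params: ModelParams) -> tuple[StrategyFreqs, float]:
    """Exact strategy fractions and the desperation rate (share below the
    threshold)."""
    counts = np.bincount(pop.strategies, minlength=3)
    freqs = StrategyFreqs.from_counts(counts[SUBMISSIVE], counts[VIOLENT], counts[EXPLOIT])
    desperation = float(np.mean(pop.resources < params.threshold))
    return freqs, desperation


def update_step(
    pop: Population,
    params: ModelParams,
    fraction: float = 0.1,
    rng: np.random.Generator | None = None,
    slave_desperate: bool = True,
) -> Population:
    """One revision step: a random ``fraction`` of agents adopts the optimal
    strategy for their resources, given the step-start frequencies.

    Frequencies are computed once at the start of the step, so agents
    updating within the same step see the same social environment. Resources
    are untouched.

    With ``slave_desperate`` (the default), agents below the threshold
    additionally act on the optimal policy every step, whatever their stored
    strategy: desperation-driven exploitation is immediate necessity, not a
    slowly revised social disposition. The exploiter fraction therefore
    tracks the desperation rate, and the slow asynchronous revision governs
    the violent/submissive choice — the population state that the violence
    dynamics and its basins of attraction live on.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    freqs, _ = measure(pop, params)
    dp = backward_induction(freqs, params)
    n = len(pop)
    k = max(1, int(round(fraction * n)))
    idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
    strategies = pop.strategies.copy()
    strategies[idx] = dp.policy[dp.grid.snap(pop.resources[idx])]
    if slave_desperate:
        desperate = pop.resources < params.threshold
        strategies[desperate] = dp.policy[dp.grid.snap(pop.resources[desperate])]
    return replace(pop, strategies=strategies)


def _resource_step(
    pop: Population, params: ModelParams, rng: np.random.Generator
) -> Population:
    # Exploratory dynamic-resource mode: apply each agent's expected-free
    # round outcome as a sampled delta, then the AR(1) reversion and shock.
    from .encounter import round_outcome_distribution

    freqs, _ = measure(pop, params)
    resources = pop.resources.copy()
    for code, strat in enumerate(STRATEGIES):
        mask = pop.strategies == code
        if not mask.any():
            continue
        dist = round_outcome_distribution(strat, freqs, params)
        draws = rng.choice(len(dist.probs), size=mask.sum(), p=dist.probs)
        resources[mask] += dist.deltas[draws]
    sd = params.sigma * np.sqrt(1.0 - params.r**2)
    resources = params.mu + params.r * (resources - params.mu) + rng.normal(0.0, sd, len(pop))
    return replace(pop, resources=resources)


def run_to_equilibrium(
    pop: Population,
    params: ModelParams,
    tol: float = 1e-4,
    window: int = 100,
    max_steps: int = 1000,
    fraction: float = 0.1,
    seed: int | None = None,
    dynamic_resources: bool = False,
    slave_desperate: bool = True,
) -> EquilibriumResult:
    """Iterate revision steps until the strategy mix stabilizes.

    Convergence: over the trailing ``window`` steps, the mean exploiter and
    violent fractions of the two half-windows differ by less than ``tol``
    (half-window averaging filters the sampling noise of partial updating).
    Non-convergence within ``max_steps`` is reported via ``converged=False``,
    not raised.
    """
    rng = np.random.default_rng(seed)
    records = []
    converged = False
    current = pop
    for step in range(1, max_steps + 1):
        current = update_step(current, params, fraction=fraction, rng=rng,
                              slave_desperate=slave_desperate)
        if dynamic_resources:
            current = _resource_step(current, params, rng)
        freqs, desperation = measure(current, params)
        records.append((step, freqs.e, freqs.v, freqs.s, desperation))
        if not np.isfinite(tol):
            converged = True
            break
        if step >= window:
            half = window // 2
            recent = np.array([r[1:3] for r in records[-half:]])
            earlier = np.array([r[1:3] for r in records[-window:-half]])
            if np.abs(recent.mean(axis=0) - earlier.mean(axis=0)).max() < tol:
                converged = True
                break
    trajectory = pd.DataFrame(
        records, columns=["step", "e", "v", "s", "desperation_rate"]
    )
    final_freqs, desperation = measure(current, params)
    return EquilibriumResult(
        final_freqs=final_freqs,
        desperation_rate=desperation,
        trajectory=trajectory,
        converged=converged,
        steps=len(records),
    )
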