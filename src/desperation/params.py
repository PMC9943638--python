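"""Parameter and strategy-frequency containers.

The model's exogenous parameters: a population of agents with Gaussian
resources (mean ``mu``, s.d. ``sigma``) evolving as an AR(1) process with
autocorrelation ``r``; a desperation threshold (fixed at 0 by default) below
which each period costs a fitness fraction ``omega``; an exploitation stake
``beta`` with sanction probability ``gamma`` and sanction cost ``pi_cost``;
a per-lost-fight fitness fraction ``lam``; mistake-attack probability ``m``;
and the number of candidate targets ``n_targets`` an exploiter samples,
which controls the efficiency of the toughness signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "STRATEGIES",
    "SUBMISSIVE",
    "VIOLENT",
    "EXPLOIT",
    "ModelParams",
    "StrategyFreqs",
]

#: Strategy labels, ordered by tie-break preference (least risky first).
STRATEGIES = ("submissive", "violent", "exploit")
SUBMISSIVE, VIOLENT, EXPLOIT = 0, 1, 2

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Exogenous model parameters with their typical defaults.

    The constraint ``(1 - gamma) * beta - gamma * pi_cost <= 0`` is enforced:
    the expected monetary payoff of exploitation against an undefended target
    must not be positive, so that stealing is never profitable on average and
    is chosen only out of desperation.
    """

    mu: float = 25.0          # mean resource level
    sigma: float = 10.0       # resource s.d.
    r: float = 0.99           # AR(1) autocorrelation of resources
    N_pop: int = 100_000      # population size
    n_targets: int = 50       # candidate targets sampled per exploiter
    beta: float = 10.0        # exploitation stake (resource units)
    pi_cost: float = 20.0     # sanction cost (resource units)
    gamma: float = 1.0 / 3.0  # sanction probability
    m: float = 0.15           # mistake-attack probability (violent agents)
    omega: float = 0.1        # per-period below-threshold fitness fraction
    lam: float = 0.1          # per-lost-fight fitness fraction
    T: int = 50               # decision horizon (periods)
    threshold: float = 0.0    # desperation threshold
    policy_tol: float = 0.12  # fitness margin exploitation must win by
    grid_lo: float | None = None   # resource grid lower edge (auto if None)
    grid_hi: float | None = None   # resource grid upper edge (auto if None)
    grid_n: int = 301              # approximate number of grid points

    def __post_init__(self) -> None:
        for name in ("gamma", "m", "omega", "lam"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} must be a probability in [0, 1]")
        if self.beta < 0 or self.pi_cost < 0:
            raise ValueError("beta and pi_cost must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.r < 1.0:
            raise ValueError("r must lie in [0, 1)")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.N_pop < 1:
            raise ValueError("N_pop must be >= 1")
        if self.grid_n < 3:
            raise ValueError("grid_n must be >= 3")
        if self.policy_tol < 0:
            raise ValueError("policy_tol must be >= 0")
        if (1.0 - self.gamma) * self.beta - self.gamma * self.pi_cost > _FREQ_TOL:
            raise ValueError(
                "exploitation must be unprofitable on average: "
                "(1 - gamma) * beta - gamma * pi_cost must be <= 0, got "
                f"{(1.0 - self.gamma) * self.beta - self.gamma * self.pi_cost:g}"
            )
        if self.grid_lo is not None and not self.grid_lo < self.threshold:
            raise ValueError("grid_lo must lie below the threshold")
        if self.grid_hi is not None and not self.grid_hi > self.threshold:
            raise ValueError("grid_hi must lie above the threshold")


@dataclass(frozen=True)
class StrategyFreqs:
    """Population fractions of the three strategies.

    ``e`` exploiters, ``v`` violent non-exploiters, ``s`` submissive;
    they must sum to one.
    """

    e: float
    v: float
    s: float

    def __post_init__(self) -> None:
        for name, p in (("e", self.e), ("v", self.v), ("s", self.s)):
            if not -_FREQ_TOL <= p <= 1.0 + _FREQ_TOL:
                raise ValueError(f"{name}={p} must lie in [0, 1]")
        if not math.isclose(self.e + self.v + self.s, 1.0, abs_tol=1e-6):
            raise ValueError(
                f"strategy fractions must sum to 1, got {self.e + self.v + self.s}"
            )

    @classmethod
    def from_counts(cls, n_sub: int, n_viol: int, n_expl: int) -> "StrategyFreqs":
        total = n_sub + n_viol + n_expl
        if total <= 0:
            raise ValueError("empty population")
        return cls(e=n_expl / total, v=n_viol / total, s=n_sub / total)

    def rounded(self, ndigits: int = 12) -> "StrategyFreqs":
        """Rounded copy, used as a cache key for policy computations."""
        e = round(self.e, ndigits)
        v = round(self.v, ndigits)
        return StrategyFreqs(e=e, v=v, s=max(1.0 - e - v, 0.0))
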