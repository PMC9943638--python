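"""State-dependent optimal decisions by stochastic dynamic programming.

An agent's state is its resource level, discretized on a uniform grid that
contains the desperation threshold exactly. Resources revert to the
population mean as an AR(1) process with autocorrelation ``r`` and Gaussian
innovations of s.d. ``sigma * sqrt(1 - r**2)`` (so the stationary law is the
population's Gaussian(mu, sigma^2)). Fitness is the terminal resource level
(floored at zero), reduced multiplicatively by a fraction ``omega`` for every
period started below the threshold and by ``lam`` for every lost fight.

Backward induction over a horizon of ``T`` periods yields the expected
fitness of each strategy at every resource level, given the population's
strategy frequencies, and hence the optimal policy. Within a period the
order of events is: strategy outcome (resource delta, fights), then the
AR(1) reversion and shock, then the next period. Exact value ties are broken
towards the less risky strategy: submissive > violent > exploit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .encounter import round_outcome_distribution
from .params import STRATEGIES, ModelParams, StrategyFreqs

__all__ = [
    "ResourceGrid",
    "DPResult",
    "build_grid",
    "transition_matrix",
    "ar1_transition",
    "backward_induction",
    "optimal_strategy",
    "policy_map",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResourceGrid:
    """Uniform resource grid containing the threshold as a grid point."""

    points: np.ndarray
    step: float

    def __len__(self) -> int:
        return len(self.points)

    def snap(self, x) -> np.ndarray:
        """Indices of the nearest grid points (clipped to the grid range)."""
        idx = np.rint((np.asarray(x) - self.points[0]) / self.step).astype(np.int64)
        return np.clip(idx, 0, len(self.points) - 1)


@lru_cache(maxsize=64)
def build_grid(params: ModelParams) -> ResourceGrid:
    """Resource grid for ``params``.

    Defaults cover [mu - 5 sigma, mu + 5 sigma] and always reach 3 sigma
    below the threshold, with roughly ``grid_n`` points. The grid is laid out
    as integer multiples of the step around the threshold so the threshold is
    a grid point exactly; nearest-point binning then keeps the dynamic
    program a proper Markov chain on the grid.
    """
    thr = params.threshold
    lo = params.grid_lo
    hi = params.grid_hi
    if lo is None:
        lo = min(params.mu - 5.0 * params.sigma, thr - 3.0 * params.sigma)
    if hi is None:
        hi = max(params.mu + 5.0 * params.sigma, thr + params.sigma)
    step = (hi - lo) / (params.grid_n - 1)
    k_lo = math.floor((lo - thr) / step)
    k_hi = math.ceil((hi - thr) / step)
    points = thr + step * np.arange(k_lo, k_hi + 1)
    return ResourceGrid(points=points, step=step)


@lru_cache(maxsize=256)
def transition_matrix(params: ModelParams, delta: float = 0.0) -> np.ndarray:
    """Row-stochastic AR(1) transition matrix on the resource grid.

    Row ``i`` is the discretized law of ``mu + r*(g_i + delta - mu) + eps``
    with ``eps ~ N(0, sigma^2 (1 - r^2))``: Gaussian probability mass binned
    at the midpoints between grid points (Tauchen's method), with mass
    beyond the grid edges lumped into the boundary bins. The outcome shift
    ``delta`` enters the conditional mean continuously, so zero-mean
    gambles stay zero-mean on the grid instead of acquiring a snapping bias.
    """
    grid = build_grid(params).points
    sd = params.sigma * math.sqrt(1.0 - params.r**2)
    means = params.mu + params.r * (grid + delta - params.mu)
    mids = (grid[:-1] + grid[1:]) / 2.0
    cdf = ndtr((mids[None, :] - means[:, None]) / sd)
    P = np.diff(np.concatenate(
        [np.zeros((len(grid), 1)), cdf, np.ones((len(grid), 1))], axis=1), axis=1)
    return P


def ar1_transition(x: float, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of next-period resources from level ``x``.

    Returns ``(grid_points, probabilities)`` for the discretized law of
    ``mu + r*(x - mu) + eps`` with ``eps ~ N(0, sigma^2 (1 - r^2))``.
    """
    grid = build_grid(params)
    sd = params.sigma * math.sqrt(1.0 - params.r**2)
    mean = params.mu + params.r * (x - params.mu)
    mids = (grid.points[:-1] + grid.points[1:]) / 2.0
    cdf = np.concatenate([[0.0], ndtr((mids - mean) / sd), [1.0]])
    return grid.points, np.diff(cdf)


@dataclass(frozen=True)
class DPResult:
    """Backward-induction output for one population composition.

    ``V0`` is the expected-fitness value at the decision time, ``Q0`` the
    per-strategy values of committing to each strategy for the first period
    (optimal play afterwards), and ``policy`` the argmax strategy code per
    grid point with the submissive > violent > exploit tie-break.
    """

    grid: ResourceGrid
    V0: np.ndarray
    Q0: np.ndarray           # shape (3, n_grid), strategy-code order
    policy: np.ndarray       # int8 codes, shape (n_grid,)
    freqs: StrategyFreqs
    params: ModelParams


@lru_cache(maxsize=512)
def _backward_induction_cached(freqs: StrategyFreqs, params: ModelParams) -> DPResult:
    grid = build_grid(params)
    pts = grid.points
    n = len(pts)

    # Per-strategy one-period operators: the outcome delta shifts the AR(1)
    # conditional mean (continuously, see transition_matrix), and lost
    # fights scale the continuation value by (1 - lam) each. Transition
    # matrices are cached per unique delta: outcome probabilities depend on
    # the population composition, the deltas do not.
    M = np.zeros((3, n, n))
    for code, strat in enumerate(STRATEGIES):
        dist = round_outcome_distribution(strat, freqs, params)
        weights = dist.probs * (1.0 - params.lam) ** dist.fights_lost
        for w, delta in zip(weights, dist.deltas):
            M[code] += w * transition_matrix(params, float(delta))

    pen = np.where(pts < params.threshold, 1.0 - params.omega, 1.0)
    V = np.maximum(pts, 0.0)  # terminal fitness, floored at zero
    Q = np.broadcast_to(V, (3, n)).copy()
    for _ in range(params.T):
        Q = M @ V
        V = pen * Q.max(axis=0)

    if not np.isfinite(V).all():
        raise FloatingPointError(
            f"backward induction produced non-finite values (freqs={freqs}, T={params.T})"
        )
    # Strategy choice: violent vs submissive by exact argmax (ties to
    # submissive, the less risky option). Exploitation must beat the best
    # safe strategy by policy_tol: its value difference rides the convex
    # kink of the floored terminal fitness, which leaves spurious
    # micro-margins (<~0.02 resource units) far above the threshold at the
    # resolution of the discretization; genuine desperation margins below
    # the threshold are an order of magnitude larger.
    safe = Q[:2].argmax(axis=0)
    q_safe = np.take_along_axis(Q[:2], safe[None, :], axis=0)[0]
    policy = np.where(Q[2] > q_safe + params.policy_tol, 2, safe).astype(np.int8)
    return DPResult(grid=grid, V0=V, Q0=pen * Q, policy=policy, freqs=freqs, params=params)


def backward_induction(freqs: StrategyFreqs, params: ModelParams) -> DPResult:
    """Solve the finite-horizon decision problem for one composition.

    Results are cached on (rounded frequencies, parameters); the computation
    is deterministic.
    """
    return _backward_induction_cached(freqs.rounded(), params)


def optimal_strategy(x: float, freqs: StrategyFreqs, params: ModelParams) -> str:
    """Optimal strategy label at resource level ``x`` (nearest grid point)."""
    dp = backward_induction(freqs, params)
    pts = dp.grid.points
    if x < pts[0] or x > pts[-1]:
        logger.warning("resource level %.3f outside grid [%.3f, %.3f]; clipping",
                       x, pts[0], pts[-1])
    return STRATEGIES[dp.policy[int(dp.grid.snap(x))]]


def policy_map(params: ModelParams, e_values, v_grid) -> pd.DataFrame:
    """Optimal strategy over (resource level, violence prevalence) per
    exploitation-prevalence panel.

    Returns a tidy frame with columns ``x, e, v, strategy``; one row per
    (grid point, e, v) combination.
    """
    e_values = list(e_values)
    v_grid = list(v_grid)
    if not e_values or not v_grid:
        raise ValueError("e_values and v_grid must be non-empty")
    rows = []
    for e in e_values:
        for v in v_grid:
            s = 1.0 - e - v
            if s < -1e-12:
                raise ValueError(f"e + v = {e + v} exceeds 1")
            dp = backward_induction(StrategyFreqs(e=e, v=v, s=max(s, 0.0)), params)
            rows.append(pd.DataFrame({
                "x": dp.grid.points,
                "e": e,
                "v": v,
                "strategy": [STRATEGIES[c] for c in dp.policy],
            }))
    return pd.concat(rows, ignore_index=True)
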