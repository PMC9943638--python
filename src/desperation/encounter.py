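"""Mean-field model of one interaction round.

Each round, every exploiter samples ``n_targets`` agents uniformly with
replacement from the population and attacks a submissive candidate if any was
drawn, otherwise a "tough" one (violent or exploiting — both fight back).
Being violent therefore deflects exploitation towards submissive agents: the
toughness signal. This module turns the population strategy fractions into
per-capita victimization rates and into the full per-round distribution of
(resource change, fights lost) faced by an agent of each strategy.

Sanction semantics: a caught exploiter (probability ``gamma``) forfeits the
loot and pays ``pi_cost``, so the expected payoff of stealing is non-positive
whenever ``(1 - gamma) * beta <= gamma * pi_cost``. In fights the disputed
``beta`` goes to the coin-toss winner first; the sanction, applied
independently, then removes the exploiter's gain and adds the fine. Mistake
fights (violent agents attacking non-exploiters with probability ``m``) carry
no resource stake; the loser only records a lost fight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import STRATEGIES, ModelParams, StrategyFreqs

__all__ = [
    "EventDistribution",
    "victimization_rates",
    "round_outcome_distribution",
    "expected_exploitation_payoff",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class EventDistribution:
    """Finite distribution over one-round outcomes.

    ``probs`` sum to one; ``deltas`` are resource changes; ``fights_lost``
    are non-negative integer counts.
    """

    probs: np.ndarray
    deltas: np.ndarray
    fights_lost: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"outcome probabilities sum to {total!r}, not 1")
        if (self.probs < -_PROB_TOL).any():
            raise ValueError("negative outcome probability")
        if (self.fights_lost < 0).any():
            raise ValueError("negative fights_lost")

    @classmethod
    def from_outcomes(cls, outcomes: list[tuple[float, float, int]]) -> "EventDistribution":
        merged: dict[tuple[float, int], float] = {}
        for p, delta, fl in outcomes:
            if p == 0.0:
                continue
            key = (float(delta), int(fl))
            merged[key] = merged.get(key, 0.0) + p
        keys = sorted(merged)
        return cls(
            probs=np.array([merged[k] for k in keys]),
            deltas=np.array([k[0] for k in keys]),
            fights_lost=np.array([k[1] for k in keys], dtype=np.int64),
        )

    def mean_delta(self) -> float:
        return float(self.probs @ self.deltas)

    def as_outcomes(self) -> list[tuple[float, float, int]]:
        return [
            (float(p), float(d), int(f))
            for p, d, f in zip(self.probs, self.deltas, self.fights_lost)
        ]


def victimization_rates(freqs: StrategyFreqs, n_targets: int) -> tuple[float, float]:
    """Expected exploitation attempts received per agent per round.

    Returns ``(rate_submissive, rate_tough)`` where "tough" covers violent and
    exploiting agents alike. Closed forms under uniform sampling with
    replacement:

    * ``rate_submissive = e * (1 - (1 - s)**n) / s`` (limit ``e * n`` as
      ``s -> 0``),
    * ``rate_tough = e * (1 - s)**(n - 1)``.

    Total attacks balance: ``s*rate_submissive + (1-s)*rate_tough = e``,
    one attempt per exploiter per round. At ``n_targets == 1`` target choice
    is blind and both rates equal ``e`` exactly.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    e, s = freqs.e, freqs.s
    if e == 0.0:
        return 0.0, 0.0
    if n_targets == 1:
        return e, e
    if s == 0.0:
        rate_sub = e * n_targets
    elif s == 1.0:
        rate_sub = e
    else:
        # (1 - (1-s)^n) / s via log1p/expm1 for accuracy at small s
        rate_sub = e * (-np.expm1(n_targets * np.log1p(-s))) / s
    rate_tough = e * (1.0 - s) ** (n_targets - 1)
    return float(rate_sub), float(rate_tough)


def _attempt_probability(rate: float) -> float:
    # Expected attack counts become at-most-one-per-round event probabilities
    # by clipping at 1; exact to O(rate^2) and expectation-conserving below it.
    return min(rate, 1.0)


def _convolve(a: list[tuple[float, float, int]], b: list[tuple[float, float, int]]):
    return [
        (pa * pb, da + db, fa + fb)
        for pa, da, fa in a
        for pb, db, fb in b
        if pa * pb > 0.0
    ]


def _fight_over(p: float, stake: float) -> list[tuple[float, float, int]]:
    """Coin-toss fight occurring with probability ``p`` over the focal
    agent's own ``stake`` resources (loser also records a lost fight)."""
    return [(1.0 - p, 0.0, 0), (p / 2.0, 0.0, 0), (p / 2.0, -stake, 1)]


def round_outcome_distribution(
    strategy: str, freqs: StrategyFreqs, params: ModelParams
) -> EventDistribution:
    """Per-round outcome distribution for a focal agent of ``strategy``.

    The focal agent is treated as measure zero: the population composition
    ``freqs`` determines its encounter probabilities regardless of its own
    strategy. Independent event classes (being victimized, own mistake
    attack, incoming mistake attacks) are convolved into one finite
    distribution.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    beta, pi, gamma, m, n = (
        params.beta,
        params.pi_cost,
        params.gamma,
        params.m,
        params.n_targets,
    )
    e, v, s = freqs.e, freqs.v, freqs.s
    rate_sub, rate_tough = victimization_rates(freqs, n)

    # Mistake fights among non-exploiters: a violent agent initiates with
    # probability m at a uniform non-exploiter; a fight happens iff the
    # target is violent too. Incoming attacks are symmetric in mean field.
    mistake_fight = m * (v / (1.0 - e)) if e < 1.0 else 0.0

    if strategy == "submissive":
        p = _attempt_probability(rate_sub)
        # Exploited with certainty when targeted; no fight. Incoming mistake
        # attacks on a submissive agent have no consequence.
        dist = [(1.0 - p, 0.0, 0), (p, -beta, 0)]
        return EventDistribution.from_outcomes(dist)

    if strategy == "violent":
        victim = _fight_over(_attempt_probability(rate_tough), beta)
        own = _fight_over(mistake_fight, 0.0)
        incoming = _fight_over(_attempt_probability(mistake_fight), 0.0)
        return EventDistribution.from_outcomes(_convolve(_convolve(victim, own), incoming))

    # Exploiter: one outgoing attempt per round, plus incoming victimization
    # (exploiters read as tough and fight back). No mistake attacks in
    # either direction: mistakes target non-exploiters only.
    q_sub = -float(np.expm1(n * np.log1p(-s))) if s < 1.0 else 1.0  # 1-(1-s)^n
    q_tough = 1.0 - q_sub
    outgoing = [
        # undefended target: theft succeeds unless sanctioned
        (q_sub * (1.0 - gamma), beta, 0),
        (q_sub * gamma, -pi, 0),
        # tough target: coin toss over the victim's beta, sanction independent
        (q_tough * 0.5 * (1.0 - gamma), beta, 0),
        (q_tough * 0.5 * gamma, -pi, 0),
        (q_tough * 0.5 * (1.0 - gamma), 0.0, 1),
        (q_tough * 0.5 * gamma, -pi, 1),
    ]
    victim = _fight_over(_attempt_probability(rate_tough), beta)
    return EventDistribution.from_outcomes(_convolve(outgoing, victim))


def expected_exploitation_payoff(params: ModelParams, freqs: StrategyFreqs) -> float:
    """Expected one-round resource change of the exploitation strategy.

    Non-positive for every population composition whenever the parameters
    satisfy ``(1 - gamma) * beta <= gamma * pi_cost``; exactly zero against a
    fully submissive population at the typical values (beta=10, pi=20,
    gamma=1/3).
    """
    return round_outcome_distribution("exploit", freqs, params).mean_delta()
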