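"""Result surfaces: policy maps, hysteresis sweeps, vector fields and the
violence-incentive curve.

The macro covariate throughout is the desperation rate — the Gaussian tail
mass below the threshold. Sweeps vary it through the mean resource level at
fixed s.d.: lowering the mean and widening the distribution move the tail
identically in this model, so one route suffices.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import SUBMISSIVE, VIOLENT, ModelParams, StrategyFreqs
from .population import init_population, measure, run_to_equilibrium, update_step
from .sdp import backward_induction, policy_map

__all__ = [
    "rate_to_mu",
    "hysteresis_sweep",
    "vector_field",
    "violence_incentive_curve",
    "policy_figure",
]


def rate_to_mu(desperation_rate: float, sigma: float) -> float:
    """Mean resource level placing a given Gaussian tail mass below zero.

    Inverts ``Phi((threshold - mu)/sigma) = rate`` at threshold 0:
    ``mu = -sigma * Phi^{-1}(rate)``.
    """
    if not 0.0 < desperation_rate < 1.0:
        raise ValueError("desperation_rate must lie strictly in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(-sigma * norm.ppf(desperation_rate))


def _at_rate(params: ModelParams, rate: float) -> ModelParams:
    return replace(params, mu=rate_to_mu(rate, params.sigma))


def hysteresis_sweep(
    params: ModelParams,
    rates,
    inits=("all_submissive", "all_violent"),
    seed: int | None = None,
    **equilibrium_kwargs,
) -> pd.DataFrame:
    """Equilibrium strategy mix against the desperation rate, per
    initialization.

    For each (rate, init) pair the population is rebuilt with the mean
    chosen by :func:`rate_to_mu` and iterated to equilibrium. Disagreement
    between the two initializations at the same rate is the bistable window;
    the all-violent branch lies weakly above the all-submissive branch
    everywhere.
    """
    rates = sorted(rates)
    seq = np.random.SeedSequence(seed)
    rows = []
    for rate in rates:
        p = _at_rate(params, rate)
        for init in inits:
            child = seq.spawn(1)[0]
            pop_seed, run_seed = [int(s) for s in child.generate_state(2) >> 1]
            pop = init_population(p, pop_seed, init)
            res = run_to_equilibrium(pop, p, seed=run_seed, **equilibrium_kwargs)
            rows.append({
                "desperation_rate_target": rate,
                "mu_used": p.mu,
                "init_label": init if isinstance(init, str) else f"fraction_violent({init})",
                "equilibrium_e": res.final_freqs.e,
                "equilibrium_v": res.final_freqs.v,
                "desperation_rate": res.desperation_rate,
                "converged": res.converged,
                "steps": res.steps,
            })
    return pd.DataFrame(rows)


def vector_field(
    params: ModelParams,
    rates,
    v0_values,
    k_steps: int = 10,
    seed: int | None = None,
    fraction: float = 0.1,
) -> pd.DataFrame:
    """Short-run drift of the violent fraction over a (rate, v0) grid.

    Each cell initializes an exact fraction ``v0`` of violent agents
    (remainder submissive; exploiters emerge endogenously from desperate
    agents at the first update), runs ``k_steps`` revision steps and records
    the change in the violent fraction. The sign structure maps the basins
    of attraction.
    """
    seq = np.random.SeedSequence(seed)
    rows = []
    for rate in sorted(rates):
        p = _at_rate(params, rate)
        for v0 in v0_values:
            child = seq.spawn(1)[0]
            pop_seed, run_seed = [int(s) for s in child.generate_state(2) >> 1]
            pop = init_population(p, pop_seed, float(v0))
            rng = np.random.default_rng(run_seed)
            start_v = measure(pop, p)[0].v
            for _ in range(k_steps):
                pop = update_step(pop, p, fraction=fraction, rng=rng)
            rows.append({
                "desperation_rate": rate,
                "v_initial": start_v,
                "delta_v": measure(pop, p)[0].v - start_v,
            })
    return pd.DataFrame(rows)


def violence_incentive_curve(
    params: ModelParams, rate: float, v_values
) -> pd.DataFrame:
    """Mean fitness advantage of violence over submission versus violence
    prevalence, at a fixed desperation rate.

    The exploiter fraction is pinned to the desperation rate (desperate
    agents exploit; see the policy map), the violent fraction is swept. For
    each composition, the advantage at a resource level is the difference in
    expected fitness between committing to violence and to submission for
    the first period with optimal play afterwards; it is averaged over the
    stationary Gaussian resource distribution.

    The curve first falls in ``v`` (more fights, negative frequency
    dependence) and then rises steeply as ``v`` approaches 1 (exploitation
    concentrates on the rare submissive agents) — the frequency-dependence
    reversal behind the bistability.
    """
    p = _at_rate(params, rate)
    e = rate
    rows = []
    for v in v_values:
        s = 1.0 - e - v
        if s < -1e-12:
            raise ValueError(f"e + v = {e + v} exceeds 1 at v={v}")
        dp = backward_induction(StrategyFreqs(e=e, v=float(v), s=max(s, 0.0)), p)
        w = norm.pdf(dp.grid.points, loc=p.mu, scale=p.sigma)
        w /= w.sum()
        incentive = float(w @ (dp.Q0[VIOLENT] - dp.Q0[SUBMISSIVE]))
        rows.append({"v": float(v), "incentive": incentive})
    return pd.DataFrame(rows)


def policy_figure(
    params: ModelParams,
    e_panels,
    v_grid,
    out_csv: str | None = None,
    out_png: str | None = None,
) -> pd.DataFrame:
    """Policy map over (resources, violence prevalence) per exploitation
    panel, optionally written to CSV and/or rendered as a figure."""
    df = policy_map(params, e_panels, v_grid)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if out_png is not None:
        _render_policy_figure(df, out_png)
    return df


def _render_policy_figure(df: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    code = {"submissive": 0, "violent": 1, "exploit": 2}
    panels = sorted(df["e"].unique())
    fig, axes = plt.subplots(1, len(panels), figsize=(5 * len(panels), 4),
                             squeeze=False, sharey=True)
    for ax, e in zip(axes[0], panels):
        sub = df[df["e"] == e]
        xs = np.sort(sub["x"].unique())
        vs = np.sort(sub["v"].unique())
        z = (sub.assign(c=sub["strategy"].map(code))
                .pivot(index="v", columns="x", values="c")
                .loc[vs, xs].to_numpy())
        ax.pcolormesh(xs, vs, z, cmap="viridis", vmin=0, vmax=2, shading="nearest")
        ax.axvline(0.0, color="white", lw=0.8)
        ax.set_title(f"e = {e:g}")
        ax.set_xlabel("resources")
    axes[0][0].set_ylabel("violence prevalence v")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
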