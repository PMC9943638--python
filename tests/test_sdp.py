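"""Dynamic-programming layer: AR(1) discretization, backward induction
against exhaustive enumeration, and policy structure."""

import numpy as np
import pytest

from desperation import (
    ModelParams,
    StrategyFreqs,
    ar1_transition,
    backward_induction,
    build_grid,
    optimal_strategy,
    policy_map,
    transition_matrix,
)
from desperation.params import EXPLOIT, STRATEGIES, SUBMISSIVE, VIOLENT
from desperation.encounter import round_outcome_distribution


def brute_force_value(freqs, params):
    """Exhaustive path enumeration of the finite-horizon decision problem.

    Plain recursion over strategies, outcomes and next-grid-state paths —
    no matrix algebra, no memoization — summing terminal fitness over every
    path. Shares only the grid, the per-delta transition rows and the
    outcome distributions with the production code.
    """
    grid = build_grid(params)
    pts = grid.points
    dists = {s: round_outcome_distribution(s, freqs, params) for s in STRATEGIES}
    rows = {
        float(d): transition_matrix(params, float(d))
        for s in STRATEGIES for d in dists[s].deltas
    }
    pen = [1.0 - params.omega if x < params.threshold else 1.0 for x in pts]

    def value(i, t):
        if t == params.T:
            return max(pts[i], 0.0)
        best = -np.inf
        for strat in STRATEGIES:
            dist = dists[strat]
            total = 0.0
            for p, delta, fl in dist.as_outcomes():
                w = p * (1.0 - params.lam) ** fl
                row = rows[float(delta)][i]
                total += w * sum(
                    row[j] * value(j, t + 1) for j in range(len(pts))
                )
            best = max(best, total)
        return pen[i] * best

    return np.array([value(i, 0) for i in range(len(pts))])


class TestGridAndTransitions:
    def test_grid_contains_threshold_exactly(self, table_params, toy_params):
        for p in (table_params, toy_params):
            g = build_grid(p)
            assert p.threshold in g.points
            assert np.all(np.diff(g.points) > 0)
            assert g.points[0] <= p.mu - 5 * p.sigma or p.grid_lo is not None
            assert g.points[0] < p.threshold < g.points[-1]

    def test_rows_are_distributions(self, small_params):
        P = transition_matrix(small_params)
        assert P.shape[0] == P.shape[1]
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_no_autocorrelation_forgets_state(self):
        p = ModelParams(r=0.0, grid_n=201)
        _, row_lo = ar1_transition(p.mu - 20, p)
        _, row_hi = ar1_transition(p.mu + 20, p)
        np.testing.assert_allclose(row_lo, row_hi, atol=1e-12)

    def test_conditional_moments(self):
        # E[next] = mu + r (x - mu); sd = sigma sqrt(1 - r^2), inflated
        # only by the step^2/12 binning variance
        p = ModelParams(mu=25.0, sigma=10.0, r=0.99)
        g, probs = ar1_transition(35.0, p)
        mean = probs @ g
        var = probs @ g**2 - mean**2
        assert mean == pytest.approx(25.0 + 0.99 * 10.0, abs=1e-6)
        step = build_grid(p).step
        assert var == pytest.approx(100.0 * (1 - 0.99**2) + step**2 / 12, rel=0.01)

    def test_stationary_distribution_is_population_gaussian(self):
        p = ModelParams(grid_n=201)
        g = build_grid(p).points
        P = transition_matrix(p)
        pi = np.full(len(g), 1.0 / len(g))
        for _ in range(600):
            pi = pi @ P
        mean = pi @ g
        sd = np.sqrt(pi @ g**2 - mean**2)
        assert mean == pytest.approx(p.mu, rel=0.01)
        assert sd == pytest.approx(p.sigma, rel=0.02)


class TestBackwardInduction:
    def test_zero_horizon_returns_floored_terminal(self, toy_params):
        import dataclasses
        p = dataclasses.replace(toy_params, T=0)
        dp = backward_induction(StrategyFreqs(0.2, 0.3, 0.5), p)
        np.testing.assert_allclose(dp.V0, np.maximum(dp.grid.points, 0.0))

    def test_equals_exhaustive_enumeration(self, toy_params):
        # 5 grid points, horizon 2: every strategy/outcome/shock path
        freqs = StrategyFreqs(e=0.2, v=0.3, s=0.5)
        dp = backward_induction(freqs, toy_params)
        expected = brute_force_value(freqs, toy_params)
        np.testing.assert_allclose(dp.V0, expected, atol=1e-12)

    def test_equals_enumeration_horizon_three(self, toy_params):
        import dataclasses
        p = dataclasses.replace(toy_params, T=3, m=0.0)
        freqs = StrategyFreqs(e=0.1, v=0.0, s=0.9)
        dp = backward_induction(freqs, p)
        expected = brute_force_value(freqs, p)
        np.testing.assert_allclose(dp.V0, expected, atol=1e-12)

    def test_value_nondecreasing_in_resources(self, small_params):
        rng = np.random.default_rng(9)
        from conftest import random_freqs
        for _ in range(5):
            dp = backward_induction(random_freqs(rng), small_params)
            assert np.all(np.diff(dp.V0) >= -1e-9)

    def test_penalties_weakly_lower_value(self, small_params):
        import dataclasses
        freqs = StrategyFreqs(0.1, 0.3, 0.6)
        base = backward_induction(freqs, small_params).V0
        for field, hi in (("omega", 0.3), ("lam", 0.3)):
            worse = backward_induction(
                freqs, dataclasses.replace(small_params, **{field: hi})).V0
            assert np.all(worse <= base + 1e-9)

    def test_degenerate_parameters_tie_to_submissive(self):
        # with no penalties, no exploiters, no mistakes and a zero stake,
        # the three strategies are payoff-identical and the least risky
        # label wins everywhere
        p = ModelParams(beta=0.0, pi_cost=0.0, gamma=0.0, omega=0.0, lam=0.0,
                        m=0.0, grid_n=101, T=10)
        dp = backward_induction(StrategyFreqs(0.0, 0.0, 1.0), p)
        assert (dp.policy == SUBMISSIVE).all()
        np.testing.assert_allclose(dp.Q0[VIOLENT], dp.Q0[SUBMISSIVE], atol=1e-9)
        np.testing.assert_allclose(dp.Q0[EXPLOIT], dp.Q0[SUBMISSIVE], atol=1e-9)

    def test_violent_equals_submissive_without_threats(self, small_params):
        # no exploiters and no mistakes: the toughness signal has nothing
        # to deflect and fights never happen
        dp = backward_induction(StrategyFreqs(0.0, 0.5, 0.5),
                                ModelParams(m=0.0, grid_n=101, T=10))
        np.testing.assert_allclose(dp.Q0[VIOLENT], dp.Q0[SUBMISSIVE], atol=1e-9)
        assert not (dp.policy == VIOLENT).any()

    def test_deterministic_recomputation(self, small_params):
        freqs = StrategyFreqs(0.05, 0.4, 0.55)
        a = backward_induction(freqs, small_params)
        from desperation.sdp import _backward_induction_cached
        _backward_induction_cached.cache_clear()
        b = backward_induction(freqs, small_params)
        np.testing.assert_array_equal(a.policy, b.policy)
        np.testing.assert_allclose(a.V0, b.V0, rtol=0, atol=0)


class TestPolicyStructure:
    def test_desperate_agents_exploit(self, table_params):
        assert optimal_strategy(-10.0, StrategyFreqs(0.05, 0.2, 0.75),
                                table_params) == "exploit"

    def test_threshold_proximity_favours_violence_under_high_exploitation(
            self, table_params):
        assert optimal_strategy(2.0, StrategyFreqs(0.3, 0.3, 0.4),
                                table_params) == "violent"

    def test_wealthy_agents_submit_at_intermediate_violence(self, table_params):
        assert optimal_strategy(60.0, StrategyFreqs(0.01, 0.4, 0.59),
                                table_params) == "submissive"

    def test_exploit_region_is_a_square(self, table_params):
        # the exploit/no-exploit boundary sits at the threshold and does
        # not move with the prevalence of violence
        bounds = []
        for v in (0.01, 0.2, 0.5, 0.7, 0.9):
            dp = backward_induction(StrategyFreqs(0.05, v, 0.95 - v), table_params)
            bounds.append(int(np.argmax(dp.policy != EXPLOIT)))
        assert max(bounds) - min(bounds) < 2

    def test_violence_margin_reverses_with_prevalence(self, table_params):
        # hawk-dove negative frequency dependence at low v turns into
        # positive feedback as submissive targets become rare
        e = 0.02
        margins = []
        for v in (0.05, 0.3, 0.6, 0.9, 0.96):
            dp = backward_induction(StrategyFreqs(e, v, 1 - e - v), table_params)
            i = int(dp.grid.snap(table_params.mu))
            margins.append(dp.Q0[VIOLENT][i] - dp.Q0[SUBMISSIVE][i])
        assert margins[1] < margins[0]
        assert margins[-1] > margins[-2] > margins[-3]

    def test_policy_map_is_complete_and_consistent(self, small_params):
        df = policy_map(small_params, [0.05], [0.1, 0.5])
        n_grid = len(build_grid(small_params))
        assert len(df) == n_grid * 2
        x = 5.0
        row = df[(df.v == 0.1) & (np.isclose(df.x, df.x[np.argmin(abs(df.x - x))]))]
        assert set(df.strategy) <= {"submissive", "violent", "exploit"}
        # single-point consistency with the scalar lookup
        lbl = optimal_strategy(x, StrategyFreqs(0.05, 0.1, 0.85), small_params)
        xs = df[df.v == 0.1]
        nearest = xs.iloc[(xs.x - x).abs().argmin()]
        assert nearest.strategy == lbl

    def test_empty_grids_rejected(self, small_params):
        with pytest.raises(ValueError):
            policy_map(small_params, [], [0.1])
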