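# Methods

## The model

The package implements a two-level model of interpersonal violence in
economically deprived communities.

**Individual level.** An agent's state is its resource level `x`, which
fluctuates as a stationary AR(1) process

    x_{t+1} = mu + r (x_t + delta_t - mu) + eps_t,
    eps_t ~ N(0, sigma^2 (1 - r^2)),

where `delta_t` is the resource consequence of the period's social
encounters. The innovation variance is chosen so that, absent encounters,
the stationary law is the population's resource distribution
N(mu, sigma^2). A *desperation threshold* sits at `x = 0`: agents below it
are "underwater" — unable to meet basic needs.

Each period an agent plays one of three strategies:

* **exploitation** — take `beta` resources from a chosen victim; with
  probability `gamma` the theft fails and a sanction `pi` is paid. Victims
  who are "tough" (violent or themselves exploiters) fight back: a coin
  toss decides who gets the disputed `beta`, the loser also pays a fight
  cost. The parameters satisfy `(1-gamma) beta <= gamma pi`, so stealing
  never pays on average — it is attractive only to the desperate, who care
  about the upside.
* **violence** — readiness to fight, observable by everyone (a *toughness
  signal*). Exploiters sample `n_targets` candidate victims and prefer
  submissive ones, so being violent deflects exploitation onto others.
  Violent agents occasionally (probability `m`) start pointless fights
  with other violent agents.
* **submission** — neither steal nor fight; an exploited submissive agent
  simply loses `beta`.

Fitness is the terminal resource level after `T` periods, floored at zero,
multiplied by `(1 - omega)` for every period started below the threshold
and by `(1 - lam)` for every lost fight. The optimal strategy at every
resource level, given the population's strategy frequencies, is computed
by backward induction on a discretized resource grid.

**Population level.** `N_pop` agents with Gaussian resources repeatedly
revise their strategies: each step a random 10% adopts the currently
optimal strategy for their own resources, given the strategy frequencies
everyone observes. Resources stay fixed during strategy convergence, so
the *desperation rate* — the Gaussian tail mass below the threshold — is
an exogenous dial, moved through `mu` (poverty) or `sigma` (inequality).

## Mean-field encounter rates

With strategy fractions `(e, v, s)` (exploiters, violent, submissive), an
exploiter's candidate sample of size `n` contains at least one submissive
agent with probability `1 - (1-s)^n`. Uniform choice within the preferred
class gives per-agent expected attack counts

    rate_submissive = e (1 - (1-s)^n) / s      (-> e n as s -> 0)
    rate_tough      = e (1-s)^(n-1)

which balance exactly: `s*rate_submissive + (1-s)*rate_tough = e`. At
`n = 1` both rates equal `e` (no target choice); as `n` grows, victimization
concentrates on the submissive — the signal's efficiency. Expected counts
are converted to at-most-one-event-per-round probabilities by clipping at 1;
below the clip this conserves expected resource flows exactly. Mistake
fights between violent agents occur at per-capita rate `m v / (1-e)` in
each direction (initiated and received) and carry no resource stake.

These rates treat the focal agent as measure zero, so the per-round outcome
distribution of *any* strategy is defined at *any* population composition —
including the payoff a hypothetical submissive deviant would face in a
fully violent population, which is what makes the high-violence equilibrium
analysable.

## Dynamic-programming numerics

* **Grid.** Uniform, ~301 points, covering `[mu - 5 sigma, mu + 5 sigma]`
  and always reaching 3 sigma below the threshold; laid out as integer
  multiples of the step around the threshold so the threshold is a grid
  point exactly.
* **Transitions.** Tauchen probability-mass binning of the Gaussian AR(1)
  kernel at bin midpoints, edge mass lumped into the boundary bins. The
  encounter delta enters the conditional mean *continuously*
  (`mu + r (g_i + delta - mu)`), one cached matrix per unique delta.
  Snapping `x + delta` to the nearest grid point first would distort the
  zero-mean theft gamble by O(step) and systematically favour exploitation;
  the continuous form keeps zero-mean gambles zero-mean while the chain
  remains a proper Markov chain on the grid.
* **Recursion.** `V_T(x) = max(x, 0)`;
  `V_t(x) = pen(x) * max_strategy E[ (1-lam)^fights * V_{t+1}(x') ]` with
  `pen(x) = 1 - omega` below the threshold, 1 otherwise. The penalty
  applies to the period's *starting* state. The terminal floor prevents
  multiplicative penalties from rewarding negative wealth.
* **Tie-breaking and the exploitation margin.** Violent vs submissive is
  an exact argmax with ties to submissive (the less risky label).
  Exploitation must beat the best safe strategy by `policy_tol` (default
  0.12 resource units). The floored terminal fitness is weakly convex, so
  the exactly-zero-mean theft gamble retains tiny positive value margins
  (up to ~0.09 at the default parameterization) in narrow bands far above
  the threshold — an artefact of the knife-edge `(1-gamma)beta = gamma pi`
  cost structure interacting with the terminal kink, not a desperation
  effect. Genuine below-threshold margins never fall under ~0.21 at any
  composition we mapped, so 0.12 separates the two regimes cleanly. The
  tolerance is calibrated for the default grid; substantially coarser
  grids inflate the discretization part of these micro-margins and need a
  larger value.
* **Horizon.** `T = 50` periods: long enough that the time-zero policy is
  numerically stationary at `r = 0.99` while keeping a backward pass at
  ~5 ms; the policy used everywhere is the time-zero column.

## Population dynamics

The revision dynamics treats the two dispositions asymmetrically:

* Agents below the threshold act on the optimal policy (exploitation,
  essentially always) *every* step. Desperation-driven crime is immediate
  necessity; the exploiter fraction therefore tracks the desperation rate
  rather than lagging it by tens of revision steps.
* Above the threshold, the violent/submissive choice — a social
  disposition — is revised asynchronously: a random 10% per step, all
  seeing the step-start frequencies, which lets the mix move smoothly
  instead of oscillating.

This makes the violent fraction `v` the system's slow state, with the
exploiter fraction slaved to the (exogenous) desperation rate — the state
space on which the vector field, the incentive curve and the hysteresis
analysis live. If instead *all* strategies are revised only through the
10% channel (`slave_desperate=False`), an all-violent population
transiently contains no exploiters at all; violence then has cost but
nothing to deflect, and the population always falls out of the
high-violence basin before exploiters appear. The basin structure itself
is unchanged — only reachability from the conventional initializations.

**Convergence.** The mix is declared stable when the means of the first
and second halves of the trailing 100-step window differ by less than
`tol = 1e-4` in both the exploiter and violent fractions (window means
filter the binomial noise of partial updating, which would keep a raw
range criterion from ever firing). Pure-state equilibria freeze exactly;
interior equilibria are frozen best-response fixed points whose location
varies by a few percent with the update path — two runs at the same rate
can legitimately stop a couple of percentage points apart.

## Parameters

| symbol | meaning | default | notes |
|---|---|---|---|
| mu | mean resources | 25 | swept via `rate_to_mu` in experiments |
| sigma | resource s.d. | 10 | inequality dial |
| r | AR(1) autocorrelation | 0.99 | persistence of (dis)advantage |
| N_pop | population size | 100 000 | 10 000 in tests/acceptance runs |
| n_targets | candidate victims | 50 | signal efficiency; hysteresis needs it high |
| beta | theft stake | 10 | |
| pi | sanction cost | 20 | |
| gamma | sanction probability | 1/3 | `(1-gamma)beta - gamma pi = 0` |
| m | mistake-attack probability | 0.15 | negative frequency dependence of violence |
| omega | below-threshold fitness fraction | 0.1 | per period |
| lam | lost-fight fitness fraction | 0.1 | per fight |
| T | decision horizon | 50 | periods |
| policy_tol | exploitation margin | 0.12 | resource units, see above |

`m`, `omega`, `lam` and `n_targets` are specified as ranges rather than
point values; the defaults were fixed once, from a mapping of the
equilibrium geometry over those ranges, at the values for which the model
exhibits its characteristic regime structure most cleanly: an inverse-S
lower branch of equilibrium violence that saturates near a desperation
rate of 0.02–0.03, a bistable window around rates 0.008–0.016 where an
all-violent history stays violent while an all-submissive one does not,
and a violence-incentive curve that falls and then explodes with
prevalence. Within the stated ranges the qualitative structure is robust;
the window's position shifts with `m * lam` (the fight-cost scale).

## What the simulations do and do not emulate

All inputs are synthetic by construction — the model has no empirical
inputs. The Gaussian-resource population with a fixed threshold at zero
captures the *mechanism* (tail mass below basic needs drives exploitation
pressure, which drives protective violence) and reproduces the qualitative
population phenomena: the poverty–violence gradient, sharp variation
between similar communities, and persistence after conditions improve.
It does not model demographic turnover, spatial structure, migration,
endogenous or relative thresholds (a `threshold` hook exists but is not
analysed), graded violence intensity, or reputations earned only through
observed fights. Resource dynamics during strategy convergence are off by
default (`dynamic_resources=True` enables them for exploration); with them
on, the desperation rate is no longer exactly exogenous. Nothing here
validates the mechanism against crime data: passing tests show internal
consistency and reproduction of the model's own predicted geometry.

## Problem sizes

Population runs in the test-suite and the acceptance script use
N = 10 000 agents (2 000 in module tests); at these sizes equilibrium
fractions differ from N = 100 000 runs only by binomial noise (~0.005),
which the assertions' tolerances absorb. A full backward pass costs ~5 ms,
an equilibrium run a few seconds, the complete test suite well under a
minute. The vector-field default of `k_steps = 10` shows short-run
tendencies; from scalar `v0` initializations the first ~3 update
generations are dominated by a composition transient (violence randomly
placed rather than concentrated near the threshold), so basin membership
is read more cleanly at `k_steps ~ 40`.
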