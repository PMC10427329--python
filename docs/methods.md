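# Methods

## Model

A fixed group of n agents repeatedly plays a continuous-action game. Agent
i's state is (xᵢ, yᵢ, x̃ᵢ, ỹᵢ): action, attitude (personal norm), empirical
expectation of the peers' mean action, and normative expectation of the
peers' mean attitude. All four are non-negative reals in action units.

Each step, every agent independently revises with probability
`revision_prob`. A revising agent posts the myopic best response to the
subjective utility

u(x) = π(x, x̃) − A₁(x−y)² − A₂(x−ỹ)² − A₃(x−x̃)² − A₄(x−G)²,

with linear marginal material payoff ∂π/∂x = D₀ + D₁x̃ − D₂x. The closed
form is

x* = max(0, [D₀ + (D₁+2A₃)x̃ + 2A₁y + 2A₂ỹ + 2A₄G] / (D₂ + 2(A₁+A₂+A₃+A₄))),

defined whenever the denominator is positive (strict concavity). Posting is
simultaneous; every agent then observes Xᵢ, the mean of the *other* n−1
posted actions (non-revisers are observed at their stale action). Revising
agents finally apply the damped linear attitude/belief update written out in
the README, using their own newly posted action in the dissonance term. The
update order — act, observe, revise beliefs — mirrors the narrative logic of
the decision cycle; the within-step coupling of action and belief revision
in a single Bernoulli draw reflects that an agent who does not reconsider
its action this round does not reconsider its beliefs either.

Sign conventions. The marginal payoff's signs are fixed so that
θ = D₀/(D₂−D₁) reproduces the three game-specific benefit-to-cost forms
(preferred action for coordination; v·b/c for the public-goods game;
2(b−c)/(d(n+1)) for the common-pool resource game). The normative penalties
carry weight Aₖ on the squared deviation with no factor ½; any consistent
alternative rescales the A's without changing the dynamics. π is
reconstructed from its marginal as D₀x + D₁x̃x − D₂x²/2 (integration
constant 0); only differences in x are ever used.

Non-negativity is enforced by clipping at zero after every action draw and
belief update. The model statement requires non-negative variables but no
mechanism; clipping is the simplest projection and is inactive at interior
equilibria.

## Games

The three named games and their (D₀, D₁, D₂) maps are tabulated in the
README. Two points are deliberate choices:

- **CPR individual cost** is linear, c·x. This is forced by consistency:
  only a linear cost yields the identical-agent Nash effort 2(b−c)/(d(n+1))
  and a D₁ term that scales with group size, both of which anchor the game.
- **CPR social optimum**: total group payoff bZ − dZ²/2 − cZ is maximised at
  *group* effort Z_opt = (b−c)/d; the per-capita optimum is (b−c)/(dn),
  making the identical-agent Nash effort exactly 2n/(n+1) times larger.

Nash baselines: the public-goods best response is uncoupled (xᵢ = θᵢ
exactly); the coordination and heterogeneous-CPR equilibria solve the linear
simultaneous first-order-condition systems directly (residual tolerance
1e-10), using the leave-self-out peer mean for consistency with the
simulator. The generic game's baseline requires D₂ > 0.

## Population sampling (what the generator emulates)

The generator reproduces the standard heterogeneous-group protocols:
per-agent game primitives are log-normal, parameterised by *distribution*
mean and sd (moment-matched: σ² = ln(1+sd²/mean²), μ = ln mean − σ²/2),
with defaults mean 1, sd 0.1 — i.e. ten-percent heterogeneity around unit
benefit-cost scales, giving mean θ = 1 for the coordination and
public-goods recipes. Public-goods shares vᵢ come from a uniform broken
stick (expected share 1/n; heavy right tail, so θᵢ = vᵢb/cᵢ is strongly
dispersed). Initial states are uniform on [0, 0.1]: groups start near
inaction, far below equilibrium.

Normative weights: base weights a₁..a₄ are log-normal(mean 1, sd 0.1) and
enter as Aₖ = ε·aₖ. At ε = 1 each normative term has, in expectation, the
same unit weight scale as the quadratic material coefficients; at ε = 0 the
model collapses to pure material best response (the
evolutionary-game-theory limit). Belief coefficients: each cell of C is
log-normal(mean 1, sd 0.1) and each row is rescaled to sum to 0.5, which
guarantees damped (hence bounded) updates while leaving relative channel
strengths heterogeneous. The underlying field-standard setup specifies the
distributions only qualitatively, so these two recipes are this package's
own defaults; both are configurable. Disabling the authority zeroes A₄ and
the third column of C before row rescaling, so the remaining channels keep
the same total inertia.

What the generator does **not** emulate: real groups have correlated traits
(e.g. cost and psychology), discrete or bounded action sets, entry/exit and
network structure, none of which are sampled here. Passing tests therefore
certify the model's internal equilibrium logic under idealised i.i.d.
heterogeneity, not predictions for any empirical population.

## Noise

"Small random errors" are implemented as independent additive Gaussian
perturbations (sd `noise_sd`, default 0.01 action units) applied to a
revising agent's new action and to each of its three updated beliefs, then
clipped at zero. Whether errors belong in actions only or also in beliefs
is underdetermined; both channels are implemented and individually
switchable (`noise_on_actions`, `noise_on_beliefs`). At the default scale
the stationary time-averages are indistinguishable from the deterministic
fixed point to ~1e-3.

## Exact equilibrium solver

With noise off and everyone revising, one step is an affine map on the
stacked 3n-vector (y, ỹ, x̃) — actions and observed means substitute in
linearly. The solver assembles the map exactly (by probing with basis
vectors, so the leave-self-out coupling is respected, not the mean-field
approximation), verifies the spectral radius of its linear part is < 1, and
solves the stationarity system directly; the certified residual must be
below 1e-10. Actions are recovered from the closed-form best response. This
replaces the literature's large-n approximation formulas (built on a
composite parameter of the rescaled best-response coefficients) with an
exact finite-n computation; the approximate corollaries survive as
properties checked through the solver:

- homogeneous θ, no authority ⇒ every variable equals θ (exact);
- no material payoffs, authority on ⇒ every variable equals G (exact);
- heterogeneous θ, no authority ⇒ group-mean action ≈ mean θ (the finite-n
  gap stays below 2% for the figure-scale recipes);
- cutting the dissonance channel (C₁₁ = 0) collapses attitude/belief
  variation while actions keep varying.

A non-contractive instance (e.g. the common-pool game at ε = 0, where the
rivalrous D₁ coupling is undamped) raises a diagnostic rather than
returning a fixed point; the simulator still runs such cases.

## Summary statistics

Per run, each agent's variables are time-averaged over the last `last_k`
recorded steps (default 100 of 1000); across-agent means and SDs and the
Kendall correlation with θ are computed per run and averaged with equal
weight across runs (per-run-then-average, not pooled). Kendall's τ-b is
used because clipping at zero makes ties likely; all-tied inputs are
flagged NaN rather than zero. The reported p-value is the across-run mean
of the per-run two-sided p-values, with significance flagged at 0.05.
Half-time — the time for the group-mean action to halve its distance to the
run's exact fixed point — is linearly interpolated between recorded steps;
runs that never reach half distance (or whose fixed point is unavailable)
are counted as censored and excluded from the average. Tightness is
reported as the coefficient of variation per variable; CVs are scale-free,
so threats or policies that rescale θ leave them unchanged.

## Problem sizes and seeds

The shipped protocols use the figure-scale sizes: n = 100 (coordination),
40 (public goods), 20 (common pool), 1000 steps, revision probability 0.5,
40-run ensembles, statistics over the last 100 steps. All randomness flows
through numpy `SeedSequence` spawning: a master seed yields per-run group
and dynamics streams, so ensembles are bitwise reproducible. Property tests
that compare the simulator against the solver use 100 random instances with
n ≤ 10 and ε ∈ [0.5, 1] (the contractive regime) at tolerance 1e-8.

## Known limitations

- The authority-backfire effect in the common-pool game (promoting the low
  social optimum raises equilibrium effort) is reproduced in direction, but
  its magnitude under the default weight distributions is small (of order
  1e-3 action units on a 0.86 baseline, assessed by paired-seed ensembles
  and the exact solver). Stronger authority columns in C produce larger
  effects; the default keeps all channels on the common scale.
- Best-response agents are myopic; no foresight, reinforcement or fictitious
  play.
- Single fixed group, one-dimensional continuous actions, continuous
  beliefs; networks, discrete beliefs and multidimensional extensions are
  out of scope.
- The stochastic dynamics are only characterised near contractive
  equilibria; non-contractive instances (low ε in rivalrous games) can
  cycle and are reported, not analysed.
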