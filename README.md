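# normdyn

Coupled dynamics of **actions, personal norms and beliefs about others** in
repeated social dilemmas: a seeded agent-based simulator plus an
analytic-equilibrium toolkit.

## The problem

When a group repeatedly faces a social dilemma — coordinating on a common
action, contributing to a public good, harvesting from a common pool —
individual behaviour is shaped by more than material payoffs. People carry a
*personal norm* about the appropriate action, an *empirical expectation* about
what peers will do, and a *normative expectation* (a second-order belief)
about what peers think is appropriate; they may also face an external
authority promoting a standard. This package implements a unified model of
how all four variables co-evolve, for researchers in cultural evolution,
behavioural economics and social-norm psychology who want a reproducible
desk-scale testbed for equilibrium predictions about group behaviour and
norm tightness/looseness.

## The model

Each agent i holds state (x, y, x̃, ỹ): action, attitude (personal norm),
empirical expectation and normative expectation, all non-negative. Actions
are chosen by myopic best response to the subjective utility

    u(x) = π(x, x̃) − A₁(x−y)² − A₂(x−ỹ)² − A₃(x−x̃)² − A₄(x−G)²

where π is the material payoff with linear marginal
∂π/∂x = D₀ + D₁x̃ − D₂x, and the A-terms are psychic costs of cognitive
dissonance, peer disapproval, non-conformity with peers' actions, and
non-conformity with an authority promoting standard G. Because u is a
concave quadratic, the best response is closed form. After acting and
observing the peers' mean action X, each agent revises attitude and beliefs
by damped linear moves:

    y'  = y  + C₁₁(x−y)  + C₁₂(X−y)  + C₁₃(G−y)      (dissonance, conformity, authority)
    ỹ'  = ỹ  + C₂₁(y−ỹ)  + C₂₂(X−ỹ)  + C₂₃(G−ỹ)      (social projection, learning, authority)
    x̃'  = x̃  + C₃₁(ỹ−x̃)  + C₃₂(X−x̃)  + C₃₃(G−x̃)      (logic constraint, learning, authority)

The composite θ = D₀/(D₂−D₁) — the best response of an agent who assumes
peers mirror its own action — summarises material benefit-to-cost and, in
several games, is the Nash effort. Named games (with per-agent heterogeneous
parameters) map onto (D₀, D₁, D₂):

| game | payoff | θ |
|---|---|---|
| coordination | bᵢ − cᵢ(x−θᵢ)² − dᵢ(x−x̃)² | θᵢ (preferred action) |
| public goods, quadratic costs | vᵢbZ − cᵢx²/2 | vᵢb/cᵢ |
| common-pool resource | (x/Z)(bZ − dZ²/2) − cᵢx | 2(b−cᵢ)/(dᵢ(n+1)) |

with Z the (predicted) group effort x + (n−1)x̃. A `generic` game takes
explicit (D₀, D₁, D₂). The package provides the stochastic simulator
(revision probability per agent per step, small Gaussian errors), an exact
3n-dimensional linear fixed-point solver for the deterministic dynamics
(with spectral-radius contraction check), evolutionary-game-theory baselines
(Nash equilibria, CPR social optimum), and ensemble summaries (means, SDs,
Kendall correlations with θ, convergence half-times, coefficients of
variation as tightness metrics).

## Worked example

The heterogeneous coordination protocol: n = 100 agents whose preferred
actions θᵢ and cost parameters cᵢ, dᵢ are log-normal with mean 1 and sd 0.1
(so mean θ = 1), no authority, normative weights at full strength (ε = 1),
revision probability 0.5, 1000 steps, statistics over the last 100 steps of
40 independent runs:

```python
import normdyn as nd

cfg = nd.PopulationConfig(game="coordination", n=100, epsilon=1.0)
sim = nd.SimConfig(steps=1000, revision_prob=0.5, noise_sd=0.01)
ens = nd.run_ensemble(cfg, sim, n_runs=40, master_seed=1)
print(nd.equilibrium_stats(ens, last_k=100).table.round(4))
```

```
         mean      sd      cv  kendall_tau  kendall_p  significant  half_time  frac_censored
x      0.9996  0.0248  0.0248       0.9095        0.0         True    18.3673            0.0
y      0.9997  0.0129  0.0129       0.7995        0.0         True    18.3673            0.0
y_exp  0.9996  0.0071  0.0071       0.6317        0.0         True    18.3673            0.0
x_exp  0.9996  0.0047  0.0047       0.4338        0.0         True    18.3673            0.0
```

All four variables equilibrate at the population mean of θ (here 1): even
attitudes and beliefs, which never enter the material payoff, align with the
materially optimal behaviour. Variation is largest for actions and smallest
for beliefs about others' actions, and the Kendall correlation with θ decays
in the same order — the model's signature ordering. The group mean halves
its distance to equilibrium in ≈ 18 steps.

The analytic side, without simulating (`normdyn predict --recipe fig5a`),
reports for the common-pool resource game (n = 20, b = 10) the predicted
mean effort θ̄ ≈ 0.88, the per-capita social optimum (b−c)/(dn) ≈ 0.46, the
contraction factor of the deterministic dynamics and the exact fixed-point
means.

A CLI wraps the same library calls:

```bash
normdyn recipes                   # list built-in figure protocols
normdyn sweep --recipe fig3a --out out/   # ε-grid ensembles, summary.csv
normdyn predict --recipe fig5b --json     # analytic report
```

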