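import numpy as np
import pytest

import normdyn as nd


@pytest.fixture(scope="session")
def coord_eps1_ensemble():
    """Full heterogeneous-coordination protocol at epsilon = 1.

    n = 100 agents with theta_pref, c, d log-normal(mean 1, sd 0.1), no
    authority, uniform [0, 0.1] initial states, revision probability 0.5,
    1000 steps, 40 independent runs.  Shared across the acceptance tests
    that examine the same ensemble.
    """
    cfg = nd.PopulationConfig(game="coordination", n=100, epsilon=1.0)
    sim = nd.SimConfig(steps=1000, revision_prob=0.5, noise_sd=0.01)
    ens = nd.run_ensemble(cfg, sim, n_runs=40, master_seed=20210819)
    return nd.equilibrium_stats(ens, last_k=100, compute_half_time=False)


@pytest.fixture(scope="session")
def pgg_eps1_ensemble():
    """Full quadratic-cost public-goods protocol at epsilon = 1 (n = 40, b = 40)."""
    cfg = nd.PopulationConfig(game="pgg_quadratic", n=40, epsilon=1.0)
    sim = nd.SimConfig(steps=1000, revision_prob=0.5, noise_sd=0.01)
    ens = nd.run_ensemble(cfg, sim, n_runs=40, master_seed=20210819)
    return nd.equilibrium_stats(ens, last_k=100, compute_half_time=False)


def random_group(rng: np.random.Generator, n_max: int = 10) -> nd.Group:
    """A small random instance across the three named games, normative
    weights strong enough that the deterministic dynamics contract."""
    game = rng.choice(["coordination", "pgg_quadratic", "cpr"])
    n = int(rng.integers(3, n_max + 1))
    eps = float(rng.uniform(0.5, 1.0))
    cfg = nd.PopulationConfig(game=game, n=n, epsilon=eps,
                              seed=int(rng.integers(2 ** 31)))
    return nd.build_group(cfg)
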