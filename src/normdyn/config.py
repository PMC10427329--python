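"""Experiment configuration: validated recipes for the standard protocols.

A recipe bundles a population config, a simulation config, a grid of epsilon
values (the normative-weight scale) and an ensemble size.  Built-in recipes
pin the parameters of the standard figure protocols:

fig2 / fig3a   Coordination, n=100, no authority
fig3b          Coordination, n=100, authority promoting G=2
fig4a / fig4b  Public goods (quadratic costs), n=40, b=40, broken-stick shares
fig5a / fig5b  Common-pool resource, n=20, b=10 (fig5b: authority G=0.5,
               the per-capita social optimum)
authority_only No material payoffs (all D=0), authority promoting G=2

Configurations are JSON files validated against a strict schema (unknown
keys rejected); a file may name a built-in recipe and override any subset of
its fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .games import GAME_NAMES
from .model_core import Authority
from .population import PopulationConfig
from .dynamics import SimConfig

__all__ = ["AuthorityModel", "PopulationModel", "SimModel", "ExperimentRecipe",
           "builtin_recipes", "get_recipe", "load_config", "config_hash"]

_EPS_GRID = [0.0, 0.25, 0.5, 0.75, 1.0]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AuthorityModel(_Strict):
    active: bool = False
    G: float = Field(default=0.0, ge=0.0)

    def build(self) -> Authority:
        return Authority(active=self.active, G=self.G)


class DistModel(_Strict):
    mean: float = Field(gt=0.0)
    sd: float = Field(ge=0.0)


class PopulationModel(_Strict):
    game: str = "coordination"
    n: int = Field(default=100, ge=2)
    authority: AuthorityModel = AuthorityModel()
    dists: dict[str, DistModel] = {}
    fixed: dict[str, float] = {}
    weight_dist: DistModel = DistModel(mean=1.0, sd=0.1)
    belief_cell_dist: DistModel = DistModel(mean=1.0, sd=0.1)
    belief_row_sum: float = Field(default=0.5, gt=0.0, le=1.0)
    init_low: float = Field(default=0.0, ge=0.0)
    init_high: float = Field(default=0.1, ge=0.0)

    def build(self, epsilon: float, seed: int = 0) -> PopulationConfig:
        if self.game not in GAME_NAMES:
            raise ValueError(f"unknown game {self.game!r}")
        return PopulationConfig(
            game=self.game, n=self.n, epsilon=epsilon,
            authority=self.authority.build(),
            dists={k: (v.mean, v.sd) for k, v in self.dists.items()} or None,
            fixed=dict(self.fixed) or None,
            weight_dist=(self.weight_dist.mean, self.weight_dist.sd),
            belief_cell_dist=(self.belief_cell_dist.mean, self.belief_cell_dist.sd),
            belief_row_sum=self.belief_row_sum, seed=seed,
        )


class SimModel(_Strict):
    steps: int = Field(default=1000, ge=1)
    revision_prob: float = Field(default=0.5, ge=0.0, le=1.0)
    noise_sd: float = Field(default=0.01, ge=0.0)
    record_every: int = Field(default=1, ge=1)
    noise_on_actions: bool = True
    noise_on_beliefs: bool = True

    def build(self, seed: int = 0) -> SimConfig:
        return SimConfig(steps=self.steps, revision_prob=self.revision_prob,
                         noise_sd=self.noise_sd, record_every=self.record_every,
                         seed=seed, noise_on_actions=self.noise_on_actions,
                         noise_on_beliefs=self.noise_on_beliefs)


class ExperimentRecipe(_Strict):
    """A fully specified experiment: population, protocol, epsilon grid, runs."""

    name: str = "custom"
    population: PopulationModel = PopulationModel()
    sim: SimModel = SimModel()
    epsilons: list[float] = Field(default_factory=lambda: list(_EPS_GRID))
    n_runs: int = Field(default=40, ge=1)
    seed: int = 0
    last_k: int = Field(default=100, ge=1)

    def model_post_init(self, _ctx) -> None:
        for e in self.epsilons:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"epsilon {e} outside [0, 1]")


def _recipe(name: str, **kw) -> ExperimentRecipe:
    return ExperimentRecipe(name=name, **kw)


def builtin_recipes() -> dict[str, ExperimentRecipe]:
    """The named experiment protocols, fully parameterised."""
    coord = dict(game="coordination", n=100)
    pgg = dict(game="pgg_quadratic", n=40, fixed={"b": 40.0})
    cpr = dict(game="cpr", n=20, fixed={"b": 10.0})
    return {
        "fig2": _recipe("fig2", population=PopulationModel(**coord),
                        epsilons=[1.0], n_runs=1),
        "fig3a": _recipe("fig3a", population=PopulationModel(**coord)),
        "fig3b": _recipe("fig3b", population=PopulationModel(
            **coord, authority=AuthorityModel(active=True, G=2.0))),
        "fig4a": _recipe("fig4a", population=PopulationModel(**pgg)),
        "fig4b": _recipe("fig4b", population=PopulationModel(
            **pgg, authority=AuthorityModel(active=True, G=2.0))),
        "fig5a": _recipe("fig5a", population=PopulationModel(**cpr)),
        "fig5b": _recipe("fig5b", population=PopulationModel(
            **cpr, authority=AuthorityModel(active=True, G=0.5))),
        "authority_only": _recipe(
            "authority_only",
            population=PopulationModel(
                game="generic", n=100,
                fixed={"D0": 0.0, "D1": 0.0, "D2": 0.0},
                authority=AuthorityModel(active=True, G=2.0)),
            epsilons=[1.0]),
    }


def get_recipe(name: str, **overrides) -> ExperimentRecipe:
    recipes = builtin_recipes()
    if name not in recipes:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(recipes)}")
    base = recipes[name]
    if overrides:
        return base.model_copy(update=overrides, deep=True)
    return base


def load_config(path, name: Optional[str] = None) -> ExperimentRecipe:
    """Load and validate a JSON experiment configuration.

    An empty file (or one without a ``name``) combined with an explicit
    ``name`` argument starts from that built-in recipe; file keys override
    recipe defaults.  Unknown keys are rejected with field-level messages.
    """
    text = Path(path).read_text().strip()
    data = json.loads(text) if text else {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a JSON object")
    base_name = data.get("name", name)
    if name is not None and "name" not in data:
        data["name"] = name
    if base_name in builtin_recipes():
        base = get_recipe(base_name).model_dump()
        _deep_update(base, data)
        data = base
    return ExperimentRecipe.model_validate(data)


def _deep_update(base: dict, new: dict) -> None:
    for k, v in new.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def config_hash(recipe: ExperimentRecipe) -> str:
    """Stable hash of the full configuration (for provenance logs)."""
    payload = json.dumps(recipe.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
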