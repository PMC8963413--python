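"""Configuration objects for the panic-buying simulator.

All model constants, need distributions, network parameters and
intervention settings are plain dataclasses with eager validation, so a
bad configuration fails before any computation starts.  Configurations
round-trip through nested dicts and YAML.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "NetworkParams",
    "ModelParams",
    "NeedsSpec",
    "InterventionConfig",
    "SimulationConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


@dataclass
class NetworkParams:
    """Interaction-network parameters.

    Attributes
    ----------
    n_agents:
        Population size N (number of netizen nodes).
    m_attach:
        Edges added per new node during preferential attachment.  The
        growth starts from a complete seed graph on ``m_attach + 1``
        nodes, so the final edge count is
        ``m_attach * (n_agents - m_attach - 1) + C(m_attach + 1, 2)``.
    leader_fraction:
        Fraction of nodes designated opinion leaders; the
        ``floor(leader_fraction * n_agents)`` highest-degree nodes get
        the role.
    """

    n_agents: int = 1000
    m_attach: int = 3
    leader_fraction: float = 0.05

    def __post_init__(self) -> None:
        _check(int(self.n_agents) == self.n_agents and self.n_agents >= 1,
               "n_agents must be a positive integer")
        # m_attach = 0 yields an edgeless graph (degenerate configurations
        # such as a single isolated agent)
        _check(int(self.m_attach) == self.m_attach and self.m_attach >= 0,
               "m_attach must be a non-negative integer")
        self.n_agents = int(self.n_agents)
        self.m_attach = int(self.m_attach)
        _check(self.n_agents >= self.m_attach + 1,
               "n_agents must be at least m_attach + 1")
        _check(0.0 <= self.leader_fraction <= 1.0,
               "leader_fraction must lie in [0, 1]")

    @property
    def n_leaders(self) -> int:
        return int(math.floor(self.leader_fraction * self.n_agents))


@dataclass
class ModelParams:
    """Behavioural model constants.

    alpha / beta weight material vs. safety need in attitude and emotion
    (alpha + beta = 1, alpha > beta following the Maslow ordering of
    physiological over safety needs).  mu scales the self-experience of
    buyers confronting shelf stock, d_sd is the supply–demand threshold,
    d_a the panic-buying attitude threshold, gamma the information-
    authenticity factor, and lambda1 / lambda2 scale the official
    response and counseling effects on material need and emotion.
    """

    alpha: float = 0.6
    beta: float = 0.4
    mu: float = 0.2
    d_sd: float = 0.65
    d_a: float = 0.6
    gamma: float = 1.0
    lambda1: float = 0.2
    lambda2: float = 0.2

    def __post_init__(self) -> None:
        _check(math.isclose(self.alpha + self.beta, 1.0, abs_tol=1e-9),
               "alpha + beta must equal 1")
        _check(self.alpha > self.beta,
               "alpha must exceed beta (material over safety need)")
        _check(0.0 < self.d_sd < 1.0, "d_sd must lie in (0, 1)")
        _check(0.0 < self.d_a < 1.0, "d_a must lie in (0, 1)")
        for name in ("mu", "gamma", "lambda1", "lambda2"):
            _check(getattr(self, name) >= 0.0, f"{name} must be non-negative")


@dataclass
class NeedsSpec:
    """Distributions of initial needs and conformity.

    Each agent draws its initial material need M0, safety need S0 and
    conformity Con(i) independently from normal distributions that are
    clipped to [0, 1].
    """

    m0_mean: float = 0.5
    m0_sd: float = 0.15
    s0_mean: float = 0.5
    s0_sd: float = 0.15
    con_mean: float = 0.5
    con_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("m0_sd", "s0_sd", "con_sd"):
            _check(getattr(self, name) >= 0.0, f"{name} must be non-negative")


@dataclass
class InterventionConfig:
    """Switches, strengths, trusts and delays of the five mechanisms.

    A disabled mechanism contributes exactly zero to every update.
    Information review and information guidance are bundled under one
    switch (review is the prerequisite for guidance).  Delays are in
    ticks; a mechanism with delay ``d`` first affects updates at tick
    ``2 + d`` (the disturbance starts at tick 1, and tick ``1 + d`` is
    the first state it can react to).
    """

    supply_enabled: bool = False
    review_guidance_enabled: bool = False
    official_enabled: bool = False
    counseling_enabled: bool = False
    q_move: float = 1.0
    gov_strength: float = 1.0
    str_pr: float = 1.0
    t_exam: int = 1
    t_timely_g: int = 1
    t_timely_p: int = 1
    tr_gov: float = 1.0
    tr_ol: float = 1.0
    tr_ordinary: float = 1.0
    post_probability: float = 1.0
    # Buyers' perceived stock: last tick's recorded stock ("previous",
    # the verbatim reading) or the stock after this tick's depletion and
    # replenishment ("current").
    perceived_stock: str = "previous"
    # First tick a mechanism with delay d acts: "next_update" -> 2 + d
    # (the first update that can use a reaction to the tick-1 state),
    # "event_plus_delay" -> 1 + d (the event starts at tick 1).
    effect_onset: str = "next_update"

    def __post_init__(self) -> None:
        _check(self.q_move >= 0.0, "q_move must be non-negative")
        _check(self.gov_strength >= 0.0, "gov_strength must be non-negative")
        if self.gov_strength > 1.0:
            warnings.warn(
                "gov_strength > 1 lies outside the nominal (0, 1) range; "
                "accepted for strong-response scenarios",
                stacklevel=2,
            )
        _check(0.0 <= self.str_pr, "str_pr must be non-negative")
        for name in ("t_exam", "t_timely_g", "t_timely_p"):
            value = getattr(self, name)
            _check(int(value) == value and value >= 0,
                   f"{name} must be a non-negative integer")
            setattr(self, name, int(value))
        for name in ("tr_gov", "tr_ol", "tr_ordinary", "post_probability"):
            _check(0.0 <= getattr(self, name) <= 1.0,
                   f"{name} must lie in [0, 1]")
        _check(self.perceived_stock in ("previous", "current"),
               "perceived_stock must be 'previous' or 'current'")
        _check(self.effect_onset in ("next_update", "event_plus_delay"),
               "effect_onset must be 'next_update' or 'event_plus_delay'")


@dataclass
class SimulationConfig:
    """Complete description of one seeded experiment."""

    network: NetworkParams = field(default_factory=NetworkParams)
    model: ModelParams = field(default_factory=ModelParams)
    needs: NeedsSpec = field(default_factory=NeedsSpec)
    interventions: InterventionConfig = field(default_factory=InterventionConfig)
    horizon: int = 100
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        for name, cls in (
            ("network", NetworkParams),
            ("model", ModelParams),
            ("needs", NeedsSpec),
            ("interventions", InterventionConfig),
        ):
            value = getattr(self, name)
            if isinstance(value, dict):
                setattr(self, name, cls(**value))
            elif not isinstance(value, cls):
                raise ConfigError(f"{name} must be a {cls.__name__} or dict")
        _check(int(self.horizon) == self.horizon and self.horizon >= 1,
               "horizon must be a positive integer")
        self.horizon = int(self.horizon)
        _check(int(self.replicates) == self.replicates and self.replicates >= 1,
               "replicates must be a positive integer")
        self.replicates = int(self.replicates)
        self.seed = int(self.seed)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        """Return a copy with top-level fields replaced."""
        return dataclasses.replace(self, **kwargs)
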