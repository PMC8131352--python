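"""Model parameters for one experimental condition.

A condition fixes the public goods game (population size ``N``, endowment
``E``, donation cost ``u``, enhancement factor ``alpha``, rounds per
generation), the punishment regime (opportunity probability ``w``, inflicted
cost and its ratio to the punisher's own cost), the mutation kernel, and the
generation schedule.  Defaults reproduce the standard study condition:
N = 100 agents, E = 50 units, u = 1 unit, alpha = 3, three rounds per
generation, 10 donations seeded in the zeroth round, 10% mutation rate with a
truncated Gaussian CCC perturbation (s.d. 5, clipped at +/-50), initial
propensities beta ~ Uniform[1, 3], and 20,000 generations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

__all__ = ["ModelParams"]

_ENDOWMENT_MODES = ("once", "per_round")
_MUTATION_MODES = ("on_adoption", "all_agents")
_W_GATE_MODES = ("generation", "per_agent")
_IMITATION_COPY_MODES = ("both", "ccc_only")


@dataclass(frozen=True)
class ModelParams:
    """All fixed parameters of one experimental condition.

    Attributes
    ----------
    n_agents : int
        Population size N.  CCC values live on the ``[0, N]`` scale.
    endowment : float
        Per-round endowment E handed to each agent.
    donation_cost : float
        Cost u of a single donation; donations are binary (an agent
        contributes exactly ``donation_cost`` or nothing in a round).
    enhancement : float
        Multiplier alpha applied to the pooled donations before equal
        redistribution.  Must satisfy ``alpha > 1`` and ``alpha / N < 1`` so
        that donating is socially efficient but individually costly.
    rounds_per_generation : int
        Number of public-goods rounds per generation.
    punish_probability : float
        w, the per-generation probability that the punishment stage runs.
    inflicted_cost : float
        Payoff decrement suffered by a punished agent (the swept "cost").
    inflicted_ratio : float
        Inflicted cost divided by the punisher's own cost; the punisher pays
        ``inflicted_cost / inflicted_ratio`` per punishment act.
    mutation_rate : float
        Per-agent probability of miscopying during reproduction.
    mutation_sd : float
        Standard deviation of the Gaussian CCC perturbation.
    mutation_clip : float
        Absolute bound applied to the drawn perturbation.
    initial_donations : int
        Donation count presented to the population in the zeroth round.
    beta_init_low, beta_init_high : float
        Bounds of the uniform distribution for initial propensities.
    beta_redraw_low, beta_redraw_high : float
        Bounds of the uniform redraw of beta when an agent mutates.
    generations : int
        Number of generations to simulate.
    endowment_accounting : str
        ``"once"`` credits E once per generation (payoff differences, which
        are all the imitation rule sees, are identical to per-round
        crediting); ``"per_round"`` adds E every round.
    carryover_nprev : bool
        If False (default), every generation's first round conditions on
        ``initial_donations`` again, so thresholds stay meaningful against
        the observed cooperation level; if True the donation count carries
        across the generation boundary.
    mutation_mode : str
        ``"on_adoption"`` (default) treats mutation as a copying error:
        only agents that adopted a role model's traits this generation can
        miscopy them (probability ``mutation_rate``).  ``"all_agents"``
        mutates every agent independently.
    w_gate : str
        ``"generation"`` gates the whole punishment stage by one Bernoulli(w)
        draw per generation (default); ``"per_agent"`` gates each agent's
        punishment opportunity independently.
    imitation_copy : str
        ``"both"`` copies the role model's CCC and beta (default);
        ``"ccc_only"`` copies CCC and keeps the imitator's beta.
    """

    n_agents: int = 100
    endowment: float = 50.0
    donation_cost: float = 1.0
    enhancement: float = 3.0
    rounds_per_generation: int = 3
    punish_probability: float = 1.0
    inflicted_cost: float = 3.0
    inflicted_ratio: float = 3.0
    mutation_rate: float = 0.1
    mutation_sd: float = 5.0
    mutation_clip: float = 50.0
    initial_donations: int = 10
    beta_init_low: float = 1.0
    beta_init_high: float = 3.0
    beta_redraw_low: float = 0.0
    beta_redraw_high: float = 3.0
    generations: int = 20_000
    endowment_accounting: str = "once"
    carryover_nprev: bool = False
    mutation_mode: str = "on_adoption"
    w_gate: str = "generation"
    imitation_copy: str = "both"

    def __post_init__(self) -> None:
        self.validate()

    @property
    def punishing_cost(self) -> float:
        """Cost the punisher pays per punishment act."""
        return self.inflicted_cost / self.inflicted_ratio

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on any violated invariant."""
        if self.n_agents < 2:
            raise ValueError("n_agents: population must contain at least 2 agents")
        if not self.enhancement > 1:
            raise ValueError(
                "enhancement: requires alpha > 1 (donating must be socially efficient)"
            )
        if not self.enhancement / self.n_agents < 1:
            raise ValueError(
                "enhancement: requires alpha / N < 1 (the per-capita share of one's "
                "own donation must not repay its cost)"
            )
        if self.donation_cost < 0:
            raise ValueError("donation_cost: must be non-negative")
        if self.endowment < 0:
            raise ValueError("endowment: must be non-negative")
        if self.rounds_per_generation < 1:
            raise ValueError("rounds_per_generation: must be >= 1")
        if not 0.0 <= self.punish_probability <= 1.0:
            raise ValueError("punish_probability: w must lie in [0, 1]")
        if self.inflicted_cost < 0:
            raise ValueError("inflicted_cost: must be non-negative")
        if not self.inflicted_ratio > 1:
            raise ValueError(
                "inflicted_ratio: punishment must hurt the target more than the "
                "punisher pays (ratio > 1)"
            )
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate: must lie in [0, 1]")
        if self.mutation_sd < 0:
            raise ValueError("mutation_sd: must be non-negative")
        if self.mutation_clip < 0:
            raise ValueError("mutation_clip: must be non-negative")
        if not 0 <= self.initial_donations <= self.n_agents:
            raise ValueError("initial_donations: must lie in [0, N]")
        if self.beta_init_low > self.beta_init_high:
            raise ValueError("beta_init_low: initial beta range is inverted")
        if self.beta_init_low < 0 or self.beta_init_high > 3:
            raise ValueError("beta_init_low/high: initial beta must lie within [0, 3]")
        if self.beta_redraw_low > self.beta_redraw_high:
            raise ValueError("beta_redraw_low: mutation beta range is inverted")
        if self.beta_redraw_low < 0 or self.beta_redraw_high > 3:
            raise ValueError("beta_redraw_low/high: mutated beta must lie within [0, 3]")
        if self.generations < 1:
            raise ValueError("generations: must be >= 1")
        if self.mutation_mode not in _MUTATION_MODES:
            raise ValueError(f"mutation_mode: must be one of {_MUTATION_MODES}")
        if self.endowment_accounting not in _ENDOWMENT_MODES:
            raise ValueError(f"endowment_accounting: must be one of {_ENDOWMENT_MODES}")
        if self.w_gate not in _W_GATE_MODES:
            raise ValueError(f"w_gate: must be one of {_W_GATE_MODES}")
        if self.imitation_copy not in _IMITATION_COPY_MODES:
            raise ValueError(f"imitation_copy: must be one of {_IMITATION_COPY_MODES}")

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model parameter(s): {sorted(unknown)}")
        return cls(**d)
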