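"""The generation engine.

One generation consists of: several public-goods rounds in which every agent
donates stochastically conditional on the previous round's donation count;
an optional punishment stage (enacted with probability ``w``) in which every
agent is matched to one random partner and may pay a personal cost to
inflict a larger cost on the partner; and synchronous reproduction, in which
every agent compares its accumulated payoff to a random role model's and
adopts the role model's traits with a Fermi probability, followed by
mutation.  Strategy change is purely imitative — the population size never
changes.

Randomness is split into named substreams (initialisation, donation
decisions, pairing, punishment, imitation, mutation) derived from one root
seed, so that switching one mechanism on or off does not perturb the draw
sequence of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .core import (
    donation_probability,
    imitation_probability,
    mutate_traits,
    pgg_round_payoffs,
    punishment_probability,
)
from .params import ModelParams

__all__ = [
    "RngStreams",
    "PopulationState",
    "GenerationRecord",
    "RunResult",
    "init_population",
    "play_round",
    "punishment_stage",
    "reproduce",
    "run_generation",
    "run_simulation",
]

_STREAM_NAMES = ("init", "decisions", "pairing", "punishment", "imitation", "mutation")


@dataclass
class RngStreams:
    """Named, independent random substreams for one simulation run."""

    init: np.random.Generator
    decisions: np.random.Generator
    pairing: np.random.Generator
    punishment: np.random.Generator
    imitation: np.random.Generator
    mutation: np.random.Generator

    @classmethod
    def from_seed(cls, seed) -> "RngStreams":
        """Build the substreams from an integer seed or a SeedSequence."""
        if not isinstance(seed, np.random.SeedSequence):
            seed = np.random.SeedSequence(seed)
        children = seed.spawn(len(_STREAM_NAMES))
        return cls(**{
            name: np.random.Generator(np.random.PCG64(child))
            for name, child in zip(_STREAM_NAMES, children)
        })


@dataclass
class PopulationState:
    """The evolving state: per-agent traits and within-generation payoffs.

    ``n_prev`` is the donation count of the most recent completed round,
    which the next round's conditional decisions are based on.
    """

    ccc: np.ndarray
    beta: np.ndarray
    payoff_acc: np.ndarray
    n_prev: int
    generation_index: int = 0

    @property
    def n_agents(self) -> int:
        return self.ccc.shape[0]

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.ccc.copy(), self.beta.copy(), self.payoff_acc.copy(),
            self.n_prev, self.generation_index,
        )


@dataclass(frozen=True)
class GenerationRecord:
    """Observables of one completed generation."""

    donations_per_round: tuple
    punishment_stage_ran: bool
    punishment_events: int
    mean_payoff: float
    donation_fraction: float


@dataclass
class RunResult:
    """Full trajectory of one replicate.

    Per-generation observables are stored as flat arrays (``donations`` has
    shape ``(generations, rounds_per_generation)``); ``records`` exposes the
    same data as one ``GenerationRecord`` per generation.
    """

    params: ModelParams
    seed: int
    donations: np.ndarray
    stage_ran: np.ndarray
    events: np.ndarray
    mean_payoffs: np.ndarray
    final_state: PopulationState

    @property
    def generations(self) -> int:
        return self.donations.shape[0]

    @cached_property
    def donation_fractions(self) -> np.ndarray:
        """Fraction of donation acts per agent-round, one entry per generation."""
        per_gen = self.params.rounds_per_generation * self.params.n_agents
        return self.donations.sum(axis=1) / per_gen

    @cached_property
    def records(self) -> list[GenerationRecord]:
        fracs = self.donation_fractions
        return [
            GenerationRecord(
                donations_per_round=tuple(int(d) for d in self.donations[g]),
                punishment_stage_ran=bool(self.stage_ran[g]),
                punishment_events=int(self.events[g]),
                mean_payoff=float(self.mean_payoffs[g]),
                donation_fraction=float(fracs[g]),
            )
            for g in range(self.generations)
        ]


def _generation_start_payoff(params: ModelParams) -> float:
    # endowment credited once per generation by default; payoff differences,
    # which drive imitation, are identical under per-round crediting
    return params.endowment if params.endowment_accounting == "once" else 0.0


def init_population(params: ModelParams, rng: np.random.Generator) -> PopulationState:
    """Draw the founding population.

    CCC ~ Uniform[1, N] (continuous), beta ~ Uniform[beta_init_low,
    beta_init_high]; payoffs start at the generation-start constant and the
    zeroth-round donation count is ``initial_donations``.
    """
    n = params.n_agents
    ccc = rng.uniform(1.0, float(n), n)
    beta = rng.uniform(params.beta_init_low, params.beta_init_high, n)
    payoff = np.full(n, _generation_start_payoff(params))
    return PopulationState(ccc, beta, payoff, int(params.initial_donations), 0)


def play_round(
    state: PopulationState, params: ModelParams, rng: np.random.Generator
) -> int:
    """One public-goods round, in place.

    Every agent donates independently with its conditional probability given
    ``state.n_prev``; round payoffs are accumulated and ``n_prev`` is
    replaced by this round's donation count, which is returned.
    """
    q_d = donation_probability(state.n_prev, state.ccc, state.beta)
    donated = rng.random(state.n_agents) < q_d
    n_donated = int(donated.sum())
    # per-agent payoff of the round: -u_i plus the equal public-good share
    # (alpha/N) * sum u_j; the endowment E enters here only in per-round
    # accounting -- differences between agents are identical either way
    share = params.enhancement / state.n_agents * n_donated * params.donation_cost
    increment = np.where(donated, share - params.donation_cost, share)
    if params.endowment_accounting == "per_round":
        increment = increment + params.endowment
    state.payoff_acc += increment
    state.n_prev = n_donated
    return n_donated


def punishment_stage(
    state: PopulationState,
    params: ModelParams,
    rng_pairing: np.random.Generator,
    rng_punishment: np.random.Generator,
) -> tuple[bool, int]:
    """The w-gated punishment stage, in place.

    With probability ``1 - w`` nothing happens.  Otherwise every agent i is
    matched to one partner j drawn uniformly from the other N - 1 agents and
    punishes with probability ``q_p(ccc_j, ccc_i, beta_i)``; a realised
    punishment costs the punisher ``punishing_cost`` and the target
    ``inflicted_cost``.  An agent can be the target of several punishers in
    the same stage.  Returns ``(stage_ran, events)``.

    The gate draw is consumed every call (even at w = 0 or 1) so the
    punishment stream advances identically across conditions.
    """
    n = state.n_agents
    if params.w_gate == "generation":
        gate_open = rng_punishment.random() < params.punish_probability
        if not gate_open:
            return False, 0
        active = np.ones(n, dtype=bool)
    else:  # per-agent gating variant
        active = rng_punishment.random(n) < params.punish_probability
        if not active.any():
            return True, 0

    # partner j drawn uniformly from the other N - 1 agents
    partners = rng_pairing.integers(0, n - 1, n)
    partners += partners >= np.arange(n)

    q_p = punishment_probability(state.ccc[partners], state.ccc, state.beta)
    punishes = active & (rng_punishment.random(n) < q_p)

    state.payoff_acc -= np.where(punishes, params.punishing_cost, 0.0)
    np.subtract.at(
        state.payoff_acc, partners[punishes], params.inflicted_cost
    )
    return True, int(punishes.sum())


def reproduce(
    state: PopulationState,
    params: ModelParams,
    rng_imitation: np.random.Generator,
    rng_mutation: np.random.Generator,
) -> None:
    """Synchronous Fermi imitation followed by mutation, in place.

    Every agent draws one role model uniformly from the other N - 1 agents
    and adopts the role model's traits with the Fermi probability of their
    payoff gap; all adoption decisions are evaluated against the pre-update
    trait vectors.  Mutation follows: in the default ``"on_adoption"`` mode
    it is a copying error — only agents that just adopted can miscopy the
    role model's traits (CCC perturbed, beta redrawn) — while
    ``"all_agents"`` mode perturbs every agent independently.  Payoffs then
    reset to the generation-start constant and the generation index
    increments; ``n_prev`` resets to ``initial_donations`` unless carryover
    is configured.
    """
    n = state.n_agents
    models = rng_imitation.integers(0, n - 1, n)
    models += models >= np.arange(n)

    q_r = imitation_probability(
        state.payoff_acc[models], state.payoff_acc, state.beta
    )
    adopts = rng_imitation.random(n) < q_r

    new_ccc = np.where(adopts, state.ccc[models], state.ccc)
    if params.imitation_copy == "both":
        new_beta = np.where(adopts, state.beta[models], state.beta)
    else:
        new_beta = state.beta

    # mutation draws are consumed for all N agents in either mode, so the
    # mutation stream stays aligned across modes
    mut_ccc, mut_beta, _ = mutate_traits(new_ccc, new_beta, params, rng_mutation)
    if params.mutation_mode == "on_adoption":
        state.ccc = np.where(adopts, mut_ccc, new_ccc)
        state.beta = np.where(adopts, mut_beta, new_beta)
    else:
        state.ccc, state.beta = mut_ccc, mut_beta

    state.payoff_acc = np.full(n, _generation_start_payoff(params))
    state.generation_index += 1
    if not params.carryover_nprev:
        state.n_prev = int(params.initial_donations)


def run_generation(
    state: PopulationState, params: ModelParams, streams: RngStreams
) -> GenerationRecord:
    """Advance the population by one full generation, in place."""
    donations = [
        play_round(state, params, streams.decisions)
        for _ in range(params.rounds_per_generation)
    ]
    stage_ran, events = punishment_stage(
        state, params, streams.pairing, streams.punishment
    )
    mean_payoff = float(state.payoff_acc.mean())
    donation_fraction = sum(donations) / (
        params.rounds_per_generation * params.n_agents
    )
    reproduce(state, params, streams.imitation, streams.mutation)
    return GenerationRecord(
        tuple(donations), stage_ran, events, mean_payoff, donation_fraction
    )


def run_simulation(params: ModelParams, seed) -> RunResult:
    """Run one replicate for ``params.generations`` generations.

    Identical ``(params, seed)`` produce bit-identical trajectories.
    """
    streams = RngStreams.from_seed(seed)
    state = init_population(params, streams.init)

    gens = params.generations
    rounds = params.rounds_per_generation
    donations = np.zeros((gens, rounds), dtype=np.int64)
    stage_ran = np.zeros(gens, dtype=bool)
    events = np.zeros(gens, dtype=np.int64)
    mean_payoffs = np.zeros(gens)

    for g in range(gens):
        for r in range(rounds):
            donations[g, r] = play_round(state, params, streams.decisions)
        ran, ev = punishment_stage(state, params, streams.pairing, streams.punishment)
        stage_ran[g] = ran
        events[g] = ev
        mean_payoffs[g] = state.payoff_acc.mean()
        reproduce(state, params, streams.imitation, streams.mutation)

    seed_int = int(seed) if np.isscalar(seed) or isinstance(seed, int) else -1
    return RunResult(
        params=params,
        seed=seed_int,
        donations=donations,
        stage_ran=stage_ran,
        events=events,
        mean_payoffs=mean_payoffs,
        final_state=state,
    )
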