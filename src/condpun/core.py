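"""Stateless building blocks of the model.

Three decisions in the model — donating, punishing, imitating — share one
functional form: a logistic (Fermi) choice probability

    p(x) = 1 / (1 + exp(-x * beta))

where ``x`` is the relevant difference (past donations minus the agent's
threshold; the target's threshold minus the punisher's; the role model's
payoff minus the imitator's) and ``beta`` is the acting agent's propensity.
``beta = 0`` makes every choice a fair coin; large ``beta`` makes the agent a
near-deterministic threshold player.

All functions here are pure, accept scalars or numpy arrays, and broadcast.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .params import ModelParams

__all__ = [
    "AgentTraits",
    "logistic",
    "donation_probability",
    "punishment_probability",
    "imitation_probability",
    "pgg_round_payoffs",
    "clamp_ccc",
    "mutate_traits",
]


class AgentTraits(NamedTuple):
    """Heritable traits of one agent.

    ``ccc`` is the conditional cooperative criterion: the previous-round
    donation count at which the agent is indifferent about donating (a low
    CCC agent donates almost regardless of the past; a CCC near N donates
    almost never).  ``beta`` is the propensity in [0, 3] governing how
    sharply the agent follows its conditional rules.
    """

    ccc: float
    beta: float


def logistic(x):
    """Overflow-safe logistic ``1 / (1 + exp(-x))``.

    Evaluated branch-wise — ``1/(1+exp(-x))`` for ``x >= 0`` and
    ``exp(x)/(1+exp(x))`` for ``x < 0`` — so the exponential argument is
    never positive: payoff gaps of thousands of units cannot overflow, and
    both tails keep full relative precision.  Returns exactly 0.5 at
    ``x = 0``.
    """
    x = np.asarray(x, dtype=float)
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def donation_probability(n_prev, ccc, beta):
    """Probability that an agent donates, given last round's donation count.

    ``q_d = 1 / (1 + exp(-(n_prev - ccc) * beta))``: the agent compares the
    observed cooperation level ``n_prev`` against its own threshold ``ccc``
    and donates with a probability that crosses 0.5 exactly at the
    threshold.  ``beta = 0`` yields 0.5 regardless.
    """
    return logistic((np.asarray(n_prev, dtype=float) - ccc) * beta)


def punishment_probability(ccc_target, ccc_punisher, beta_punisher):
    """Probability that a punisher sanctions a randomly matched target.

    ``q_p = 1 / (1 + exp(-(ccc_target - ccc_punisher) * beta_punisher))``:
    agents punish partners whose threshold exceeds their own (likelier free
    riders), and the willingness-to-donate and willingness-to-punish of an
    agent are governed by the same traits.
    """
    return logistic((np.asarray(ccc_target, dtype=float) - ccc_punisher) * beta_punisher)


def imitation_probability(payoff_model, payoff_self, beta_self):
    """Fermi (pairwise-comparison) adoption probability.

    ``q_r = 1 / (1 + exp(-(payoff_model - payoff_self) * beta_self))``: the
    imitator adopts the role model's traits with a probability increasing in
    the payoff gap, at steepness given by the imitator's own beta.
    """
    return logistic((np.asarray(payoff_model, dtype=float) - payoff_self) * beta_self)


def pgg_round_payoffs(contributions, params: ModelParams) -> np.ndarray:
    """Per-agent payoffs of one linear public goods round.

    Agent i receives ``(E - u_i) + (alpha / N) * sum_j u_j``: the withheld
    part of the endowment plus an equal, non-excludable share of the
    enhanced pool.  Every agent gets the identical public-good share, so a
    non-donor ends the round exactly ``donation_cost`` ahead of a donor.

    ``contributions`` must contain only 0 or ``params.donation_cost``
    (donations are all-or-nothing), one entry per agent.
    """
    u = np.asarray(contributions, dtype=float)
    if u.shape != (params.n_agents,):
        raise ValueError(
            f"contributions must have shape ({params.n_agents},), got {u.shape}"
        )
    valid = (u == 0.0) | (u == params.donation_cost)
    if not valid.all():
        raise ValueError(
            "contributions must be 0 or donation_cost for every agent "
            "(donations are binary)"
        )
    share = params.enhancement / params.n_agents * u.sum()
    return (params.endowment - u) + share


def clamp_ccc(ccc, n_agents: int):
    """Clamp CCC onto [0, N].

    The boundary values are meaningful strategies: CCC = 0 is an
    unconditional cooperator, CCC = N an unconditional free rider.
    """
    return np.clip(ccc, 0.0, float(n_agents))


def mutate_traits(ccc, beta, params: ModelParams, rng: np.random.Generator):
    """Apply the mutation kernel to per-agent trait arrays.

    Each agent independently mutates with probability ``mutation_rate``.  A
    mutating agent has a perturbation ``delta ~ Normal(0, mutation_sd)``,
    clipped to ``[-mutation_clip, +mutation_clip]``, added to its CCC (then
    clamped to [0, N]) and its beta replaced by a fresh draw from
    ``Uniform(beta_redraw_low, beta_redraw_high)``.  Non-mutating agents are
    returned unchanged.

    Draws are consumed for every agent regardless of the mutation mask, so
    the stream position after the call depends only on the population size.

    Returns ``(ccc_new, beta_new, mutated_mask)`` as numpy arrays.
    """
    ccc = np.atleast_1d(np.asarray(ccc, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n = ccc.shape[0]
    mutated = rng.random(n) < params.mutation_rate
    delta = rng.normal(0.0, params.mutation_sd, n)
    np.clip(delta, -params.mutation_clip, params.mutation_clip, out=delta)
    beta_new_draws = rng.uniform(params.beta_redraw_low, params.beta_redraw_high, n)
    ccc_new = clamp_ccc(np.where(mutated, ccc + delta, ccc), params.n_agents)
    # clamp only where mutated, so out-of-range inputs pass through untouched
    ccc_new = np.where(mutated, ccc_new, ccc)
    beta_new = np.where(mutated, beta_new_draws, beta)
    return ccc_new, beta_new, mutated
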