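# Model and methods

## The model

`condpun` simulates the cultural evolution of cooperation and altruistic
punishment in a well-mixed population of *heterogeneous conditional
cooperators* playing a repeated linear public goods game (PGG).

Each of the `N` agents carries two heritable traits:

- **CCC** (conditional cooperative criterion), a threshold on the `[0, N]`
  scale: the previous-round donation count at which the agent is
  indifferent about donating.  Low CCC agents behave like altruists, high
  CCC agents like free riders, intermediate ones like conditional
  cooperators.
- **β** (propensity) in `[0, 3]`: the steepness with which the agent
  follows its conditional rules.  β = 0 makes every decision a fair coin;
  β = 3 makes the agent a near-deterministic threshold player.

All three decisions in the model share one logistic (Fermi) form
`p = 1 / (1 + exp(−x·β))` where `x` is the relevant difference:

1. **Donation** (`x = n_C − CCC_i`): in each round the agent donates one
   unit (cost `u = 1`) with a probability increasing in the previous
   round's donation count `n_C`.  The pooled donations are multiplied by
   `α = 3` and shared equally by all `N` agents regardless of contribution
   (`α > 1`, `α/N < 1`: donating is socially efficient, individually
   costly).
2. **Punishment** (`x = CCC_j − CCC_i`): after the last round of a
   generation, with probability `w`, every agent is matched to one
   uniformly drawn partner and may pay a cost `x_p` to inflict a cost
   `3·x_p` on the partner.  Because the probability increases in the
   partner's threshold relative to one's own, agents who are more willing
   to donate are also more willing to punish, and likelier free riders are
   likelier targets.  The swept "cost" axis of the experiments is the
   *inflicted* cost (inflicted 3 ⇒ punisher pays 1).
3. **Imitation** (`x = π_j − π_i`): at the end of the generation every
   agent draws one role model and adopts the model's (CCC, β) pair with
   the Fermi probability of their total payoff gap, all updates applied
   synchronously against the pre-update traits.  Mutation follows (see
   below), payoffs reset, and the next generation begins.

A generation is three PGG rounds, one optional punishment stage, one
imitation/mutation step.

## Default parameters (the study condition)

| parameter | default | meaning |
|---|---|---|
| `n_agents` | 100 | population size; also the upper bound of the CCC scale |
| `endowment` | 50 | per-round endowment E (payoff-difference neutral) |
| `donation_cost` | 1 | unit donation u |
| `enhancement` | 3 | public-good multiplier α |
| `rounds_per_generation` | 3 | PGG rounds per generation |
| `initial_donations` | 10 | donation count seeding the first round |
| `punish_probability` | 1 | w, per-generation probability of the punishment stage |
| `inflicted_cost` | 3 | payoff decrement of a punished agent |
| `inflicted_ratio` | 3 | inflicted / punishing cost (punisher pays cost/3) |
| `mutation_rate` | 0.1 | per-copy miscopy probability |
| `mutation_sd` | 5 | s.d. of the Gaussian CCC perturbation |
| `mutation_clip` | 50 | absolute bound on a single perturbation |
| `beta_init_low/high` | 1, 3 | initial β ~ Uniform[1, 3] |
| `beta_redraw_low/high` | 0, 3 | mutated β ~ Uniform(0, 3) |
| `generations` | 20,000 | generations per replicate |

Initial CCC is continuous Uniform[1, N].  CCC is clamped to `[0, N]` after
every perturbation, so unconditional cooperators (CCC = 0) and
unconditional free riders (CCC = N) are reachable boundary strategies.
The experiment grid defaults to `w ∈ {1, 0.5} × inflicted cost ∈ {3, 0.9}`
with 20 replicates per cell.

## Resolved ambiguities (behavioral switches)

Four mechanics of the verbal model description admit more than one
faithful implementation.  Each is a config switch; the defaults are the
readings under which the simulator reproduces the published summary
statistics, and each alternative is one flag away for sensitivity
analysis.

- **`carryover_nprev` (default False).**  Each generation's first round
  conditions on `initial_donations` (= 10) again rather than on the last
  round of the previous generation.  Under carryover, `n_C` saturates near
  `N` once cooperation establishes and *every* threshold below ~`N` issues
  identical behavior — the conditional-cooperation gradient the model is
  built on disappears, and the population grinds to mean CCC ≈ 2
  regardless of condition.  The reset reading keeps thresholds binding
  against the observed cooperation level every generation and yields the
  condition-dependent compositions the model is known for.
- **`mutation_mode` (default `"on_adoption"`).**  Mutation is a *copying
  error*: an agent that adopted its role model's traits miscopies them
  with probability 0.1 (CCC perturbed by a clipped `Normal(0, 5)` draw, β
  replaced by a fresh `Uniform(0, 3)` draw).  The alternative
  (`"all_agents"`) perturbs every agent independently at 10% per
  generation.  The copy-error reading matters for β: an independent 10%
  uniform redraw pins the population mean β near 1.5 in every condition,
  whereas under copy-error β is free to respond to selection — it falls
  toward ~0.8 under strong punishment (w = 1, cost 3) and rises toward
  ~2.2 under weak punishment, which is what the published β patterns show,
  and it is what lets the CCC composition spread across conditions
  (means ≈ 8 to 17) instead of clustering at 15–18.
- **`w_gate` (default `"generation"`).**  One Bernoulli(w) draw gates the
  entire punishment stage per generation; the `"per_agent"` variant gates
  each agent's opportunity independently (same expectation, lower
  variance).
- **`imitation_copy` (default `"both"`).**  Adoption copies the role
  model's CCC *and* β; `"ccc_only"` is available for sensitivity analysis.
- **`endowment_accounting` (default `"once"`).**  E enters each agent's
  payoff once per generation instead of once per round.  Imitation sees
  only payoff *differences*, so the two modes generate identical dynamics;
  the switch only shifts the reported mean payoff by `(rounds − 1)·E`.

## Randomness and reproducibility

One root seed per run is expanded (via `numpy` `SeedSequence` spawning)
into six named substreams: initialisation, donation decisions, partner
pairing, punishment, imitation, mutation.  Streams are consumed a fixed
number of draws per generation regardless of outcomes (e.g. mutation draws
are generated for all N agents even when only adopters may use them), so
toggling one mechanism does not perturb the draw sequence of the others.
Identical `(params, seed)` give bit-identical trajectories.  Sweep cells
derive their seeds from `(root_seed, w, cost, replicate)`, so any single
cell rerun in isolation reproduces its row exactly, independent of grid
shape or execution order.

## Numerical choices

- The logistic is evaluated branch-wise (`1/(1+e^{−x})` for `x ≥ 0`,
  `e^{x}/(1+e^{x})` otherwise) so the exponential argument is never
  positive: payoff gaps of any magnitude cannot overflow, both tails keep
  full relative precision, and the indifference point returns exactly 0.5.
- Mutation perturbations are clipped (not resampled) at ±`mutation_clip`;
  at the default s.d. 5 the ±50 bound is ~10σ and the two conventions are
  observationally indistinguishable.
- The median of an even-sized population is the midpoint of the two
  central order statistics.  CCC histograms use half-open width-10 bins
  with the last bin closed at `N`, so `CCC = N` free riders are counted.
- The asymptotic donation fraction averages the last 10% of generations by
  default (`tail_fraction` configurable); trajectories are stationary long
  before that window at the default run length.
- Partner and role-model draws exclude the self by drawing from `N − 1`
  integers and shifting indices at or above the drawer's own.

## What the acceptance protocol computes

`scripts/acceptance.py` reruns the full study protocol (four grid
conditions × 20 replicates × 20,000 generations, ~2.5 s per replicate on
one core) and reports the indifference-point donation probability, the
replicate-averaged final mean CCC per condition, and the replicate-averaged
final median CCC at (w = 1, cost = 3).  The orderings across conditions —
stronger punishment regimes select lower thresholds and sustain more
cooperation, and cooperation collapses entirely at w = 0 — are stable
across seeds; the per-condition means carry replicate-to-replicate spread
of roughly ±1–3 CCC units (largest at w = 1, cost = 3, where individual
replicates range over ~2–16).

## Known limitations

- At the weakest punishment regime simulated (w = 0.5, inflicted cost
  0.9), this implementation equilibrates at a replicate-averaged mean CCC
  of ≈ 15–18 by 20,000 generations, below the published ≈ 32 for that
  condition; the published value sits closer to the initial population
  mean (~50) than any variant of the mechanics we tested reaches, and the
  orderings across conditions are unaffected.  The cell is reported as
  computed.
- The population is well-mixed: no spatial or network structure, and no
  demography (pure imitation dynamics; population size is constant).
- Donations are binary (one unit or nothing); there are no continuous
  contribution levels and no alternative update rules (Fermi imitation
  only).
- Punishment is threshold-based, not action-based: an agent that just
  donated can still be punished by a lower-threshold partner.  This is a
  property of the model, not an implementation artifact.
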