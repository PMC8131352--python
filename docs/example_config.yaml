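# Complete annotated configuration for condpun.
# Every value shown here is the default; delete any line to keep it.

model:
  n_agents: 100            # population size N (CCC lives on [0, N])
  endowment: 50.0          # per-round endowment E (payoff-difference neutral)
  donation_cost: 1.0       # cost u of one binary donation
  enhancement: 3.0         # public-good multiplier alpha (alpha > 1, alpha/N < 1)
  rounds_per_generation: 3
  punish_probability: 1.0  # w: per-generation probability of the punishment stage
  inflicted_cost: 3.0      # payoff decrement of a punished agent (the swept "cost")
  inflicted_ratio: 3.0     # inflicted / punishing cost; punisher pays cost/ratio
  mutation_rate: 0.1       # per-copy miscopy probability
  mutation_sd: 5.0         # s.d. of the Gaussian CCC perturbation
  mutation_clip: 50.0      # absolute bound on one perturbation
  initial_donations: 10    # donation count seeding each generation's first round
  beta_init_low: 1.0       # initial propensity ~ Uniform[low, high]
  beta_init_high: 3.0
  beta_redraw_low: 0.0     # mutated propensity ~ Uniform[low, high]
  beta_redraw_high: 3.0
  generations: 20000
  # behavioral switches (see docs/methods.md for the rationale):
  endowment_accounting: once     # once | per_round (identical dynamics)
  carryover_nprev: false         # true carries n_C across generations
  mutation_mode: on_adoption     # on_adoption (copy error) | all_agents
  w_gate: generation             # generation | per_agent
  imitation_copy: both           # both | ccc_only

sweep:
  w_values: [1.0, 0.5]
  inflicted_costs: [3.0, 0.9]
  replicates: 20
  root_seed: 0

output:
  out_dir: condpun_out
  stride: 20               # thinning of the donation-fraction time series
  tail_fraction: 0.1       # window of the asymptotic donation fraction
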