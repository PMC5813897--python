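# Desk-scale reference configuration: the calibrated 25x25 profile with the
# severe contaminated-injury parameter set and the reference patient seed.
model:
  profile: small
run:
  params:
    invasiveness: 2.0
    toxigenesis: 5.0
    host_resilience: 0.1
    environmental_toxicity: 2.0
    injury_radius: 8
  seed: 7
  max_steps: 4000
ga:
  population_size: 20
  generations: 6
  replicates: 10
  stall_generations: 6
  rng_seed: 5
outcomes:
  n_seeds: 100
  n_reseeds: 100
  snapshot_step: 100
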