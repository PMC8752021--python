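# Desk-scale replicator learning twin on a 30x30 lattice.
# Starts from a marginally viable parameter set: the full-scale unfavorable
# start lies beyond the desk lattice's viability edge (all-extinct runs
# read the odd-point fallback and give the learner no gradient).
seed: 1
output_dir: results/replicator-learn-small
record_every: 200
parameters:
  - {name: alpha_A, kind: positive, initial: 0.15,  description: replicase length penalty}
  - {name: beta_A,  kind: positive, initial: 2.5,   description: replicase activity scale}
  - {name: gamma_A, kind: positive, initial: 200.0, description: replicase half-saturation}
  - {name: alpha_B, kind: positive, initial: 0.15,  description: fidelity length penalty}
  - {name: beta_B,  kind: positive, initial: 2.5,   description: fidelity activity scale}
  - {name: gamma_B, kind: positive, initial: 200.0, description: fidelity half-saturation}
  - {name: beta_C,  kind: positive, initial: 1.5,   description: metabolic activity scale}
  - {name: gamma_C, kind: positive, initial: 5.0,   description: metabolic half-saturation}
learning: {rate: 0.2, rounds: 30, strategy: gradient}
objective:
  testbed: replicator
  readout: mean_replicator_length
  reference_step: 2000
  extinction_fallback: 5.0
replicator_world: {lattice_side: 30}
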