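# Learning mean replicator length at step 100e4 from the unfavorable start.
seed: 1
output_dir: results/replicator-learn
parameters:
  - {name: alpha_A, kind: positive, initial: 0.2,   description: replicase length penalty}
  - {name: beta_A,  kind: positive, initial: 2.0,   description: replicase activity scale}
  - {name: gamma_A, kind: positive, initial: 200.0, description: replicase half-saturation}
  - {name: alpha_B, kind: positive, initial: 0.2,   description: fidelity length penalty}
  - {name: beta_B,  kind: positive, initial: 2.0,   description: fidelity activity scale}
  - {name: gamma_B, kind: positive, initial: 200.0, description: fidelity half-saturation}
  - {name: beta_C,  kind: positive, initial: 1.0,   description: metabolic activity scale}
  - {name: gamma_C, kind: positive, initial: 5.0,   description: metabolic half-saturation}
learning: {rate: 0.2, rounds: 60, strategy: gradient}
objective:
  testbed: replicator
  readout: mean_replicator_length
  reference_step: 1000000
  extinction_fallback: 5.0
replicator_world: {lattice_side: 100}
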