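# Progressive learning: stage objectives at steps 10/20/40/100e4, 15 rounds each.
seed: 1
output_dir: results/progressive
parameters:
  - {name: alpha_A, kind: positive, initial: 0.2,   description: replicase length penalty}
  - {name: beta_A,  kind: positive, initial: 2.0,   description: replicase activity scale}
  - {name: gamma_A, kind: positive, initial: 200.0, description: replicase half-saturation}
  - {name: alpha_B, kind: positive, initial: 0.2,   description: fidelity length penalty}
  - {name: beta_B,  kind: positive, initial: 2.0,   description: fidelity activity scale}
  - {name: gamma_B, kind: positive, initial: 200.0, description: fidelity half-saturation}
  - {name: beta_C,  kind: positive, initial: 1.0,   description: metabolic activity scale}
  - {name: gamma_C, kind: positive, initial: 5.0,   description: metabolic half-saturation}
learning: {rate: 0.2, strategy: gradient}
objective_schedule:
  - {testbed: replicator, readout: mean_replicator_length, reference_step: 100000,  rounds: 15, extinction_fallback: 5.0}
  - {testbed: replicator, readout: mean_replicator_length, reference_step: 200000,  rounds: 15, extinction_fallback: 5.0}
  - {testbed: replicator, readout: mean_replicator_length, reference_step: 400000,  rounds: 15, extinction_fallback: 5.0}
  - {testbed: replicator, readout: mean_replicator_length, reference_step: 1000000, rounds: 15, extinction_fallback: 5.0}
replicator_world: {lattice_side: 100}
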