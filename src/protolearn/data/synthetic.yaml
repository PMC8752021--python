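# Closed-form concave validation surface with a known optimum.
seed: 1
output_dir: results/synthetic
parameters:
  - {name: q1, initial: 0.75}
  - {name: q2, initial: 0.01}
  - {name: q3, initial: 0.2}
  - {name: q4, initial: 0.08}
  - {name: q5, initial: 0.03}
  - {name: q6, initial: 0.008}
  - {name: q7, initial: 0.15}
  - {name: q8, initial: 0.6}
learning: {rate: 0.1, rounds: 200, strategy: gradient}
objective:
  testbed: synthetic
  readout: synthetic_value
  synthetic:
    optimum: [0.3, 0.05, 0.4, 0.01, 0.2, 0.002, 0.5, 0.1]
    weights: [1.0, 0.5, 2.0, 1.0, 1.5, 0.7, 1.0, 1.2]
    noise_sd: 0.0
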