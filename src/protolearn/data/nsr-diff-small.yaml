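# Desk-scale NSR-minus-control twin (over-fitting control schedule).
seed: 1
output_dir: results/nsr-diff-small
record_every: 500
parameters:
  - {name: PNF,  initial: 4.0e-3, description: non-enzymatic nucleotide formation}
  - {name: PNFR, initial: 0.02,   description: NSR-catalyzed nucleotide formation}
  - {name: PND,  initial: 1.0e-3, description: free-nucleotide decay}
  - {name: PRL,  initial: 2.0e-5, description: random ligation}
  - {name: PBB,  initial: 1.0e-5, description: bond breaking}
  - {name: PAT,  initial: 0.5,    description: template-directed attachment}
  - {name: PFP,  initial: 0.1,    description: false pairing}
  - {name: PMV,  initial: 1.0e-3, description: movement}
learning: {rate: 0.5, rounds: 30, strategy: gradient}
objective:
  testbed: nsr
  readout: nsr_minus_ctrl
  reference_step: 2500
  inoculations:
    - {species: nsr, copies: 30, step: 200}
    - {species: ctrl, copies: 30, step: 200}
nsr_world: {grid_side: 10, total_material: 4000, end_decay: 0.004}
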