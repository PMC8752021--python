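# Learning the NSR-minus-control difference (the over-fitting control setup).
seed: 1
output_dir: results/nsr-diff
parameters:
  - {name: PNF,  initial: 4.0e-3, description: non-enzymatic nucleotide formation}
  - {name: PNFR, initial: 0.02,   description: NSR-catalyzed nucleotide formation}
  - {name: PND,  initial: 1.0e-3, description: free-nucleotide decay}
  - {name: PRL,  initial: 2.0e-5, description: random ligation}
  - {name: PBB,  initial: 1.0e-5, description: bond breaking}
  - {name: PAT,  initial: 0.5,    description: template-directed attachment}
  - {name: PFP,  initial: 0.1,    description: false pairing}
  - {name: PMV,  initial: 1.0e-3, description: movement}
learning: {rate: 0.5, rounds: 50, strategy: gradient}
objective:
  testbed: nsr
  readout: nsr_minus_ctrl
  reference_step: 150000
  inoculations:
    - {species: nsr, copies: 100, step: 10000}
    - {species: ctrl, copies: 100, step: 10000}
nsr_world: {grid_side: 30, total_material: 40000}
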