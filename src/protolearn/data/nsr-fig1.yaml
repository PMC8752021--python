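# Spread of a single inoculated NSR under the favorable reference parameters.
seed: 1
output_dir: results/nsr-fig1
record_every: 1000
parameters:
  - {name: PNF,  initial: 2.0e-4, description: non-enzymatic nucleotide formation}
  - {name: PNFR, initial: 0.9,    description: NSR-catalyzed nucleotide formation}
  - {name: PND,  initial: 0.01,   description: free-nucleotide decay}
  - {name: PRL,  initial: 2.0e-6, description: random ligation}
  - {name: PBB,  initial: 1.0e-6, description: bond breaking}
  - {name: PAT,  initial: 0.1,    description: template-directed attachment}
  - {name: PFP,  initial: 0.01,   description: false pairing}
  - {name: PMV,  initial: 0.01,   description: movement}
objective:
  testbed: nsr
  readout: nsr_count
  reference_step: 150000
  inoculations:
    - {species: nsr, copies: 1, step: 10000}
nsr_world: {grid_side: 30, total_material: 40000}
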