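# protolearn

Automatic parameter exploration for stochastic evolutionary simulators.

Monte-Carlo models of early molecular evolution — RNA pools, replicator
lattices — depend on parameters (reaction probabilities, activity
coefficients) that prebiotic chemistry cannot yet pin down.  Research in
this area therefore often runs *in reverse*: search the parameter space for
values under which a hypothesized scene (say, the spread of a nucleotide
synthetase ribozyme) actually happens, and treat those values as a
prediction to be judged against future chemical knowledge.  Done by hand,
that search is slow and hard to report.  `protolearn` automates it.

## The method

Let `O = Model{p_1, …, p_n}` be a scalar readout of one simulation run.
One learning round evaluates the base run and, for each parameter, one run
with that parameter alone perturbed by the learning rate `e` in its
remembered direction, giving changes `ΔO_i`.  All parameters then update
simultaneously and multiplicatively, normalized by `M = max_i |ΔO_i|`:

    p_i ← p_i · (1 + e · g_i / M)        (slope g_i = s_i ΔO_i ≥ 0)
    p_i ← p_i · (1 − e · |g_i| / M)      (g_i < 0, additive form)

so the most influential parameter takes the full step `(1±e)` and the rest
move in proportion to their measured potential.  The next round probes each
parameter in the direction it just moved.  Variants: a multiplicative
downward form `p/(1+e)`, a downward default after zero change, coordinate
ascent over seven geometric candidates per parameter, descent, and a
progressive (transfer-learning) schedule of objectives at successively
later simulation steps, each stage warm-started from the last.

The explorers are scikit-learn-style estimators
(`GradientAscentExplorer`, `CoordinateAscentExplorer`,
`ProgressiveExplorer`) with `fit`, `get_params`/`set_params` and fitted
attributes (`params_`, `trace_`, `objective_value_`).

Two origin-of-life testbeds are included as first-class simulators:

* **RNA-pool (NSR) testbed** — a toroidal grid of rooms with precursors,
  free nucleotides and explicit RNA sequences; a motif-defined nucleotide
  synthetase ribozyme catalyzes local nucleotide formation, molecules
  ligate, break, erode, template-copy (with false pairing) and move.  Eight
  event probabilities are the exploration targets; total material is
  exactly conserved.
* **Replicator lattice testbed** — a toroidal lattice of composition-vector
  replicators with trans-acting replicase/fidelity/metabolic activities
  `a_X = β_X · l_X/(l_X+γ_X) · e^{−α_X L}`; eight activity-curve parameters
  are the targets and mean replicator length is the readout (with an
  "odd-point" fallback of 5 on extinction).

## Worked example

```python
from protolearn import GradientAscentExplorer, nsr
from protolearn.objectives import ObjectiveSpec, Inoculation

spec = ObjectiveSpec(                      # NSR count at step 2500 on the
    testbed="nsr", readout="nsr_count",    # desk-scale 10x10 world, after
    reference_step=2500,                   # inoculating 30 NSR at step 200
    world_config=nsr.NSRWorldConfig.small(),
    inoculations=(Inoculation("nsr", 30, 200),),
)
exp = GradientAscentExplorer(learning_rate=0.5, rounds=30, seed=1).fit(spec)
print(round(exp.trace_.records[0].base_objective),
      round(exp.objective_value_))
print({k: float(f"{v:.2g}") for k, v in exp.best_params_.items()})
```

prints

```
17 72
{'PNF': 0.003, 'PNFR': 0.01, 'PND': 0.0028, 'PRL': 1.3e-07,
 'PBB': 3.2e-06, 'PAT': 0.1, 'PFP': 0.00085, 'PMV': 0.0066}
```

Starting from a parameter set under which the inoculated ribozyme declines
(objective 17), thirty rounds of exploration find a setting sustaining a
four-times larger population (objective 72): the learner pushed the
false-pairing and random-ligation probabilities down by orders of
magnitude, reduced bond breaking, and slowed template attachment
fivefold.  Note
that the catalyzed formation rate `PNFR` did *not* increase — with a plain
count objective, parameter settings that favor any replicating species
also favor the ribozyme, so its catalytic function is not actually
selected for.  That is precisely why the `nsr_minus_ctrl` objective and
the knock-out control exist.

A command-line interface wraps the same library for config-file driven
runs: `protolearn explore <config.yaml>`, `protolearn simulate
<config.yaml>`, `protolearn report <trace.tsv>`.  Reference configurations
(full scale and desk scale) ship in `src/protolearn/data/` and are loadable
with `protolearn.bundled_config(name)`.  All tabular output is TSV; every
run records its seed and config hash for bit-identical reruns.

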