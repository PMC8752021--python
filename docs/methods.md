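# Methods

## The exploration algorithm

`protolearn` tunes the parameters `p_1 … p_n` of a stochastic simulator to
maximize a scalar readout `O = Model{p_1, …, p_n}` of one simulation run.
Nothing about the simulator is assumed beyond "in-bounds parameters in,
finite number out", which is what makes the approach usable for Monte-Carlo
evolutionary models whose gradients are inaccessible.

One learning round costs `n + 1` evaluations:

1. **Base run** — evaluate `O` at the current parameter set.
2. **Probes** — for each parameter `i`, evaluate `O_i` with parameter `i`
   alone perturbed by the learning rate `e`: upward `p_i (1+e)`, or downward
   when the direction memory says so (`p_i (1−e)` in the additive form,
   `p_i / (1+e)` in the multiplicative form).  `ΔO_i = O_i − O`.
3. **Normalized simultaneous update** — with `g_i = s_i ΔO_i` the slope with
   respect to increasing `p_i` (`s_i` the probe direction) and
   `M = max_i |ΔO_i|`:

       p_i ← p_i · (1 + e·g_i/M)            if g_i ≥ 0
       p_i ← p_i · (1 − e·|g_i|/M)          if g_i < 0   (additive form)
       p_i ← p_i / (1 + e·|g_i|/M)          if g_i < 0   (multiplicative form)

   The parameter with the largest |ΔO| moves by the full factor; the others
   move in proportion to their measured potential.  If `M = 0` the round is
   a no-op (the update would divide by zero; in practice this occurs only
   for degenerate, e.g. constant, objectives).
4. **Direction memory** — the next round probes each parameter in the
   direction it just moved; a parameter whose probe left the objective
   unchanged is probed upward next time (downward under the
   `zero_change_direction="down"` variant).

The testing rate and the update rate share the single value `e`
deliberately: probing much more finely than one intends to step buys
gradient precision the step cannot use, and stepping much further than one
probed extrapolates the measurement.  `e` is *not* annealed.  The method's
purpose is to locate a good parameter region for a hypothesized scene, not
to polish an optimum; near the optimum a fixed `e` produces a visible limit
cycle whose amplitude grows with `e` (see *Known limitations*).

**Coordinate ascent** evaluates, per parameter in a fixed order, the
incumbent value and up to six geometric candidates `p(1±e)^k`, `k = 1..3`
(candidates outside the bounds are dropped), installs the argmax, and moves
to the next parameter.  The incumbent is re-evaluated at every visit: the
objective is stochastic, and comparing fresh candidate draws against a stale
cached incumbent value would bias the argmax toward whichever noise
realization produced it.  Ties break to the incumbent, then to the earlier
candidate.

**Progressive learning** runs gradient-ascent stages against objectives read
at successively later simulation steps, each stage warm-started from the
previous stage's final parameters *and* direction memory.  It trades a small
risk (early-step optima need not match late-step optima) for a large saving
in simulation steps, and is a transfer-learning schedule in miniature.

**Descent** is ascent on the negated objective; the trace records the
maximized (signed) values, so a descent run on `O` is bit-identical to an
ascent run on `−O`.

## Parameter domains

All updates are multiplicative, so an exact zero is absorbing.  Probability
parameters therefore live on `[1e-12, 1]`, generic positive reals on
`[1e-12, 1e6]`.  Out-of-bounds updates clamp to the nearest bound and emit a
`ClampWarning`; clamping (rather than rejection) preserves the simultaneous
character of the update.

## Randomness and reproducibility

A master seed plus a structural key — (round, evaluation slot, replicate) —
derives an independent child generator for every objective evaluation via
`numpy` seed-sequence spawning.  Identical config + seed gives bit-identical
traces.  Fresh randomness per evaluation is the default: the probe
differences `ΔO_i` then carry the full simulation noise, which matches how
the method is meant to operate on Monte-Carlo models.  A
common-random-numbers switch (one stream per round) exists for variance-
reduction experiments; it is off by default and is of limited value for
agent-based simulations, where a parameter change quickly decorrelates the
draw sequence anyway.

## The synthetic validation surface

`bundled_synthetic()` is a log-quadratic concave surface
`O = −Σ_i w_i (ln p_i − ln p*_i)² (+ Gaussian noise)` over eight probability
parameters, with optima spread over four orders of magnitude
(0.002 … 0.5), uneven curvature weights (0.5 … 2), and starting values
within a factor of 10 of the optimum on both sides.  The maximum is 0 at a
known `p*`, so recovery error is directly measurable.  The log-quadratic
form matches the multiplicative geometry of the update rule without
informing it of anything else.  Optima and starts are interior to the
bounds on purpose: a recovery target within one probe step of a hard bound
measures the clamp behavior, not convergence (see *Known limitations*).

## The RNA-pool (NSR) testbed

A square torus of rooms holds raw-material precursors, free nucleotides
(counts per base over A/U/C/G) and RNA molecules (explicit sequences).  A
**nucleotide synthetase ribozyme (NSR)** is any molecule containing a fixed
10-nt motif; a control (**Ctrl**) motif of the same length identifies a
catalytically inert species.  Eight per-step probabilities drive the events,
in a fixed order per step: formation (`PNF`, or `PNFR` in rooms holding a
functional NSR — catalysis *replaces* the spontaneous rate), decay of free
nucleotides (`PND`), random ligation of disjoint random pairs (`PRL`; free
nucleotides participate as length-1 molecules), end decay (see *Strand
turnover* below), bond breaking of single strands (`PBB` per internal bond;
duplexes are protected), template-directed
synthesis (`PAT` per molecule to append the next nascent nucleotide, wrong
base with probability `PFP`; a completed complement detaches with
probability 0.5 per step), and movement to a von Neumann neighbor room
(`PMV`).  Material-producing events precede consumers, and the fixed order
makes trajectories deterministic under a fixed stream.

Bookkeeping invariant: precursors + free nucleotides + all strand residues
(templates and nascent prefixes) is exactly constant; inoculated molecules
are exogenous and are added to the conservation ledger.

Choices worth naming:

- **Replication is two-step.**  A template's complement is a different
  molecule (motif containment is checked on the literal sequence), so an
  NSR count rises only when complements are themselves copied back.  This
  is the standard plus/minus-strand replication cycle.
- **Counting convention.**  Every template strand containing the motif
  counts toward the NSR/Ctrl readouts, whether or not it currently carries a
  nascent complement; nascent strands are never counted (they are different
  molecules in the making).  The alternative — counting single strands only
  — makes the readout measure the instantaneous duplex fraction rather than
  the population: under fast-attachment regimes a 100-molecule inoculum
  reads as ~10 while ~90 templates are busy copying, and the readout then
  rewards parameters that idle templates instead of parameters that
  preserve them.
- **Strand turnover.**  Besides the explored bond-breaking probability, a
  fixed world constant ``end_decay`` erodes one terminal residue per event
  back into the free pool — the nascent strand first in a duplex, so a
  stalled copy aborts and frees its template rather than locking material
  forever.  Without a degradation channel molecules are immortal: an
  inoculated species can never decline (the defining unfavorable regime),
  and dead junk polymers absorb all material into a parameter-insensitive
  jam.  The default is 0.001 per step at full scale and 0.004 in the
  desk-scale twin, matching its compressed timescale.
- **Extension needs material.**  An attachment event consumes one free
  nucleotide of the required base from the molecule's room; if none is
  present the event fails.  Error bases are drawn uniformly from the three
  non-complementary bases.
- **Knockout** (`knockout=True`) removes catalytic function (`PNFR` is never
  applied) while leaving motif identity — the over-fitting control: any
  NSR-vs-Ctrl difference that survives knockout would be an artifact.
- Defaults: 30×30 grid with 40,000 material units at full scale; the
  desk-scale twin (`NSRWorldConfig.small()`) is 10×10 with 4,000 units.
  Motifs are fixed arbitrary 10-mers that are not each other's complement.

## The lattice replicator testbed

RNA-like replicators occupy sites of a square torus.  A replicator is a
composition vector over monomer classes A (replicase), B (fidelity), C
(metabolic) and N (neutral); length `L` is the total count.  Activities
follow `a_X = β_X · l_X/(l_X + γ_X) · exp(−α_X L)` with `α_C = 0` — β
scales, γ half-saturates in the devoted monomer count, α penalizes total
length.  Activities act strictly in *trans*: a replicator's chance to be
copied depends on its Moore neighbors' activities, never its own, which
creates the cooperator/cheater tension that makes spatial structure (limited
dispersal) matter.

Per sweep: every empty site runs a lottery among its Moore-neighbor
replicators with claim weight `W(T) = S_A(T)·(1+S_C(T))/(1+L_T/λ)` (`S_X`
sums activity X over T's neighbors; λ is the claim length scale), filling
with probability `min(1, ΣW/K)`; the winner is copied with per-monomer error
rate `ε₀/(1+S_B(T))`, each error reassigning a monomer's class or (with
probability `indel_fraction`) inserting/deleting one monomer, length never
below 1.  Then decay (probability `d` per replicator) and dispersal (swap
with a random von Neumann neighbor site with probability `D`).

The qualitative contract of this testbed is the contrast between the
favorable activity parameters (`α = 0.1, β_A = β_B = 3, β_C = 2`: mean
length grows well above its initial value of 5) and the unfavorable ones
(`α = 0.2, β = 2, β_C = 1`: mean length stagnates).  The world constants
(`d`, `D`, `ε₀`, `K`, λ, occupancy) were chosen once so that this contrast
is expressed in the travelling-cluster regime — abundant empty space, claim
probabilities far from saturation — and are *not* exploration targets.

## Scaled-down study conditions

Full-scale runs (150,000-step RNA-pool trajectories, 10⁶-sweep lattices,
hundreds of learning rounds) exceed what a test suite should spend.  The
package therefore ships desk-scale twins of every reference configuration;
the tests and the acceptance script run exclusively on these:

- NSR learning twin: 10×10 grid, 4,000 material units, 30 NSR molecules
  inoculated at step 200, objective read at step 2,500, learning rate 0.5
  for 30 rounds.  The inoculum is scaled with the material budget so that
  inoculated residues stay well below the world total, and the window spans
  roughly 1.5 erosion half-lives so that decline and spread separate
  cleanly.
- NSR difference twin: the same schedule with 30 NSR + 30 Ctrl inoculated
  and the NSR−Ctrl readout.
- Replicator twin: 30×30 lattice, 5,000 sweeps — enough for the favorable
  activity parameters to roughly double the mean length while the
  unfavorable ones fail to sustain the population.  On the small lattice
  the unfavorable setting is beyond the viability edge and goes extinct
  (reading the odd-point fallback) rather than stagnating as it would on a
  larger lattice; the bundled desk-scale *learning* configurations
  therefore start from a documented marginally viable parameter set, since
  an all-extinct start returns the identical fallback for every probe and
  yields a zero gradient everywhere.

What passing at desk scale does and does not show: the twins preserve the
qualitative regimes (decline of an inoculated species under unfavorable
parameters, spread under favorable ones; length growth vs stagnation) but
not the paper-scale absolute numbers — a 4,000-unit world simply cannot
hold thousands of NSRs.  Improvement factors and contrasts, not absolute
counts, are the meaningful desk-scale quantities.

## Known limitations

- **Fixed-`e` limit cycle.**  Because the best parameter always takes the
  full multiplicative step, a converged run oscillates around the optimum
  with relative amplitude of order `e` instead of settling.  At `e = 0.1`
  the cycle is within a few percent per coordinate on the synthetic
  surface; at `e = 0.2` individual coordinates periodically sit 6–25% off.
  This is inherent to the method (no annealing by design).
- **Bound trap.**  A probability parameter sitting exactly at its upper
  bound, with upward direction memory, probes to a clamped no-op, measures
  `ΔO = 0`, and keeps probing upward — it can only leave the bound if
  another parameter's motion changes the landscape, or under the
  `zero_change_direction="down"` variant.
- **Noise-dominated rounds.**  When the objective's replicate noise exceeds
  the true per-probe differences, the update direction is random and the
  parameters random-walk (multiplicatively) until they reach a region with
  detectable gradient.  Larger `e`, replicate averaging, or larger worlds
  all raise the signal; the desk-scale defaults accept some of this walk as
  the price of speed, exactly as visible in the full-scale learning curves.
- **Reconstructed testbeds.**  Both simulators are reconstructions built
  from the mechanisms their parameters name, not ports of the original
  models; absolute readout levels are not comparable to the original
  publications' figures, and only qualitative regimes are contracted.
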