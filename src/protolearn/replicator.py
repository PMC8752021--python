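"""Lattice replicator simulator with three trans-acting activity classes.

RNA-like "replicators" occupy sites of a square torus.  Each replicator is a
composition vector of monomer classes: A (replicase), B (fidelity), C
(metabolic) and N (neutral); its length ``L`` is the total monomer count.
Class activities follow a saturating, length-penalized curve

    a_X = beta_X * l_X / (l_X + gamma_X) * exp(-alpha_X * L)

with no length penalty for class C (``alpha_C = 0``).  Activities act in
*trans*: a replicator's replication chances depend on the activities of its
Moore neighbors, never on its own.  This creates the cooperation/selection
tension that makes limited dispersal matter — with strong mixing, cheaters
(short replicators that contribute little) share the benefits of their
neighbors' activities, while weak mixing keeps cooperative clusters
together.

Per sweep, in fixed order: (1) every empty site runs a replication lottery
among its Moore-neighbor replicators, with claim weight

    W(T) = S_A(T) * (1 + S_C(T)) / (1 + L_T / lambda)

where ``S_X(T)`` sums activity X over T's neighbors and ``lambda`` is the
claim length scale (longer templates copy slightly slower); the site fills with
probability ``min(1, total_weight / K)`` and the winner is copied with a
per-monomer error rate ``eps0 / (1 + S_B(T))`` (errors reassign a monomer's
class, or — with probability ``indel_fraction`` — insert/delete one
monomer); (2) each replicator decays with probability ``d``; (3) each
replicator swaps with a random von Neumann neighbor site with probability
``D`` (the dispersal rate).

The eight activity-curve parameters (alpha/beta/gamma for A and B,
beta/gamma for C) are the exploration targets; the world constants
(lattice size, decay, dispersal, error rates, claim scales) are held fixed.
The default constants place the system in a travelling-cluster regime —
abundant empty space (decay 0.1 against sub-saturated claims), weak
dispersal, and a claim-speed penalty mild enough that selection on the
activity curves, not on copy speed alone, decides which compositions
spread.  In this regime the favorable activity parameters drive mean
length well above its initial value while the unfavorable ones do not
sustain the population at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parameters import ParameterDef, ParameterSet

__all__ = [
    "ReplicatorParams",
    "ReplicatorWorldConfig",
    "ReplicatorWorld",
    "parameter_defs",
    "activity",
    "init_world",
    "step",
    "run",
    "save_snapshot",
    "load_snapshot",
]

#: Exploration starting values: the unfavorable setting under which mean
#: replicator length stagnates near its initial value.
_DEFAULT_INITIALS = {
    "alpha_A": 0.2,
    "beta_A": 2.0,
    "gamma_A": 200.0,
    "alpha_B": 0.2,
    "beta_B": 2.0,
    "gamma_B": 200.0,
    "beta_C": 1.0,
    "gamma_C": 5.0,
}

#: The favorable reference setting (replicator lengths grow markedly).
FAVORABLE = {
    "alpha_A": 0.1,
    "beta_A": 3.0,
    "gamma_A": 200.0,
    "alpha_B": 0.1,
    "beta_B": 3.0,
    "gamma_B": 200.0,
    "beta_C": 2.0,
    "gamma_C": 5.0,
}

PARAM_NAMES = tuple(_DEFAULT_INITIALS)

_DESCRIPTIONS = {
    "alpha_A": "length penalty of replicase activity",
    "beta_A": "scale of replicase activity",
    "gamma_A": "half-saturation monomer count of replicase activity",
    "alpha_B": "length penalty of fidelity activity",
    "beta_B": "scale of fidelity activity",
    "gamma_B": "half-saturation monomer count of fidelity activity",
    "beta_C": "scale of metabolic activity (no length penalty)",
    "gamma_C": "half-saturation monomer count of metabolic activity",
}


def parameter_defs(initials: dict[str, float] | None = None) -> tuple[ParameterDef, ...]:
    """The eight explorable activity-curve parameters (positive reals)."""
    vals = dict(_DEFAULT_INITIALS)
    if initials:
        unknown = set(initials) - set(vals)
        if unknown:
            raise ValueError(f"unknown replicator parameters: {sorted(unknown)}")
        vals.update(initials)
    return tuple(
        ParameterDef(name=n, initial=vals[n], kind="positive", description=_DESCRIPTIONS[n])
        for n in PARAM_NAMES
    )


@dataclass(frozen=True)
class ReplicatorParams:
    """Activity-curve parameters; note there is no ``alpha_C``."""

    alpha_A: float
    beta_A: float
    gamma_A: float
    alpha_B: float
    beta_B: float
    gamma_B: float
    beta_C: float
    gamma_C: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_parameter_set(cls, params: ParameterSet) -> "ReplicatorParams":
        return cls(**{n: params[n] for n in PARAM_NAMES})

    @classmethod
    def favorable(cls) -> "ReplicatorParams":
        return cls(**FAVORABLE)


@dataclass(frozen=True)
class ReplicatorWorldConfig:
    """Lattice geometry and the fixed (non-explored) model constants."""

    lattice_side: int = 100
    initial_occupancy: float = 0.3
    initial_length: int = 5
    decay_prob: float = 0.1
    dispersal_prob: float = 0.05
    base_error: float = 0.05
    indel_fraction: float = 0.2
    claim_scale: float = 2.0
    claim_length_scale: float = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_side < 3:
            raise ValueError("lattice_side must be >= 3")
        if not (0.0 <= self.initial_occupancy <= 1.0):
            raise ValueError("initial_occupancy must be in [0, 1]")
        if self.initial_length < 1:
            raise ValueError("initial_length must be >= 1")
        for name in ("decay_prob", "dispersal_prob", "base_error", "indel_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.claim_scale <= 0:
            raise ValueError("claim_scale must be > 0")
        if self.claim_length_scale <= 0:
            raise ValueError("claim_length_scale must be > 0")

    @classmethod
    def small(cls, **overrides) -> "ReplicatorWorldConfig":
        """Desk-scale configuration (30x30 lattice)."""
        merged = {"lattice_side": 30, **overrides}
        return cls(**merged)


@dataclass
class ReplicatorWorld:
    """Lattice state: per-site monomer-class counts (0 everywhere off-site)."""

    config: ReplicatorWorldConfig
    occ: np.ndarray  # (S, S) bool
    lA: np.ndarray  # (S, S) int64
    lB: np.ndarray
    lC: np.ndarray
    lN: np.ndarray
    step_count: int = 0

    def lengths(self) -> np.ndarray:
        """Lengths of all living replicators (1-D array)."""
        L = self.lA + self.lB + self.lC + self.lN
        return L[self.occ]

    @property
    def population(self) -> int:
        return int(self.occ.sum())


def activity(l, L, alpha: float, beta: float, gamma: float):
    """Saturating, length-penalized activity curve.

    ``beta`` scales, ``gamma`` half-saturates in the devoted monomer count
    ``l``, and ``alpha`` penalizes total length ``L`` exponentially.  Class C
    uses ``alpha = 0``.  Accepts scalars or arrays.
    """
    l = np.asarray(l, dtype=float)
    L = np.asarray(L, dtype=float)
    return beta * (l / (l + gamma)) * np.exp(-alpha * L)


def init_world(config: ReplicatorWorldConfig, rng: np.random.Generator) -> ReplicatorWorld:
    """Random occupancy; every initial replicator is (A,B,C,N) = (1,1,1,2).

    The deterministic initial composition (length ``initial_length`` with one
    monomer of each active class) keeps fixtures reproducible.
    """
    s = config.lattice_side
    occ = rng.random((s, s)) < config.initial_occupancy
    extra_n = max(0, config.initial_length - 3)
    has3 = config.initial_length >= 3
    lA = np.where(occ, 1 if has3 else 0, 0).astype(np.int64)
    lB = np.where(occ, 1 if config.initial_length >= 2 else 0, 0).astype(np.int64)
    lC = np.where(occ, 1 if has3 else 0, 0).astype(np.int64)
    if config.initial_length < 3:
        # degenerate tiny replicators: put everything in A then B
        lA = np.where(occ, 1, 0).astype(np.int64)
        lB = np.where(occ, config.initial_length - 1, 0).astype(np.int64)
        lC = np.zeros_like(lA)
        extra_n = 0
    lN = np.where(occ, extra_n, 0).astype(np.int64)
    return ReplicatorWorld(config=config, occ=occ, lA=lA, lB=lB, lC=lC, lN=lN)


_MOORE = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _moore_sum(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for di, dj in _MOORE:
        out += np.roll(np.roll(x, di, axis=0), dj, axis=1)
    return out


def _activities(world: ReplicatorWorld, params: ReplicatorParams):
    L = world.lA + world.lB + world.lC + world.lN
    with np.errstate(invalid="ignore", divide="ignore"):
        aA = np.where(world.occ, activity(world.lA, L, params.alpha_A, params.beta_A, params.gamma_A), 0.0)
        aB = np.where(world.occ, activity(world.lB, L, params.alpha_B, params.beta_B, params.gamma_B), 0.0)
        aC = np.where(world.occ, activity(world.lC, L, 0.0, params.beta_C, params.gamma_C), 0.0)
    return L, aA, aB, aC


def _copy_with_errors(
    counts: np.ndarray, eps_eff: float, config: ReplicatorWorldConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy a composition vector (A,B,C,N) applying the error model."""
    child = counts.copy()
    n_err = rng.binomial(int(child.sum()), eps_eff) if eps_eff > 0 else 0
    for _ in range(n_err):
        total = int(child.sum())
        if rng.random() < config.indel_fraction:
            if rng.random() < 0.5:  # insertion
                child[rng.integers(0, 4)] += 1
            elif total > 1:  # deletion; length never drops below 1
                src = rng.choice(4, p=child / total)
                child[src] -= 1
        else:  # class reassignment
            src = rng.choice(4, p=child / total)
            child[src] -= 1
            child[rng.integers(0, 4)] += 1
    return child


def step(
    world: ReplicatorWorld, params: ReplicatorParams, rng: np.random.Generator
) -> ReplicatorWorld:
    """One whole-lattice sweep: replication, decay, dispersal."""
    cfg = world.config
    s = cfg.lattice_side

    # (1) replication lotteries at empty sites, from the pre-sweep state
    if world.occ.any():
        L, aA, aB, aC = _activities(world, params)
        SA = _moore_sum(aA)
        SC = _moore_sum(aC)
        SB = _moore_sum(aB)
        W = np.where(
            world.occ, SA * (1.0 + SC) / (1.0 + L / cfg.claim_length_scale), 0.0
        )
        stack = np.stack(
            [np.roll(np.roll(W, di, axis=0), dj, axis=1) for di, dj in _MOORE]
        )
        total = stack.sum(axis=0)
        empty = ~world.occ
        p_fill = np.where(empty, np.minimum(1.0, total / cfg.claim_scale), 0.0)
        fill = empty & (rng.random((s, s)) < p_fill)
        if fill.any():
            # categorical winner draw over the 8 neighbor contributions
            u = rng.random((s, s)) * total
            cum = np.cumsum(stack, axis=0)
            winner = (cum <= u[None, :, :]).sum(axis=0)
            winner = np.minimum(winner, 7)
            for i, j in zip(*np.nonzero(fill)):
                k = int(winner[i, j])
                di, dj = _MOORE[k]
                pi, pj = (i - di) % s, (j - dj) % s
                if not world.occ[pi, pj]:
                    continue  # zero-weight corner: no parent there
                counts = np.array(
                    [world.lA[pi, pj], world.lB[pi, pj], world.lC[pi, pj], world.lN[pi, pj]],
                    dtype=np.int64,
                )
                eps_eff = cfg.base_error / (1.0 + SB[pi, pj])
                child = _copy_with_errors(counts, eps_eff, cfg, rng)
                world.lA[i, j], world.lB[i, j], world.lC[i, j], world.lN[i, j] = child
                world.occ[i, j] = True

    # (2) decay
    if cfg.decay_prob > 0.0:
        die = world.occ & (rng.random((s, s)) < cfg.decay_prob)
        if die.any():
            world.occ[die] = False
            for arr in (world.lA, world.lB, world.lC, world.lN):
                arr[die] = 0

    # (3) dispersal: swap with a random von Neumann neighbor site
    if cfg.dispersal_prob > 0.0:
        movers = world.occ & (rng.random((s, s)) < cfg.dispersal_prob)
        idx = np.nonzero(movers)
        if idx[0].size:
            dirs = rng.integers(0, 4, size=idx[0].size)
            offsets = ((1, 0), (-1, 0), (0, 1), (0, -1))
            for t in range(idx[0].size):
                i, j = int(idx[0][t]), int(idx[1][t])
                di, dj = offsets[int(dirs[t])]
                ni, nj = (i + di) % s, (j + dj) % s
                for arr in (world.occ, world.lA, world.lB, world.lC, world.lN):
                    arr[i, j], arr[ni, nj] = arr[ni, nj], arr[i, j]

    world.step_count += 1
    return world


def run(
    world: ReplicatorWorld,
    params: ReplicatorParams,
    n_steps: int,
    *,
    rng: np.random.Generator,
    record_every: int = 100,
    fallback: float = 5.0,
):
    """Run ``n_steps`` sweeps; returns the recorded time series.

    Columns: step, population, mean_length, mean_aA, mean_aB, mean_aC.
    ``mean_length`` falls back to ``fallback`` when the population is zero
    (the "odd point" convention of the governing objective).
    """
    import pandas as pd

    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rows = []

    def _record(t: int) -> None:
        pop = world.population
        if pop:
            _, aA, aB, aC = _activities(world, params)
            mean_len = float(world.lengths().mean())
            means = (
                float(aA[world.occ].mean()),
                float(aB[world.occ].mean()),
                float(aC[world.occ].mean()),
            )
        else:
            mean_len = float(fallback)
            means = (0.0, 0.0, 0.0)
        rows.append((t, pop, mean_len, *means))

    _record(0)
    for t in range(1, n_steps + 1):
        step(world, params, rng)
        if t % record_every == 0 or t == n_steps:
            _record(t)
    return pd.DataFrame(
        rows,
        columns=["step", "population", "mean_length", "mean_aA", "mean_aB", "mean_aC"],
    )


# ---------------------------------------------------------------------------
# plain-text snapshots


def save_snapshot(world: ReplicatorWorld, path) -> None:
    """One occupied site per line: site index, l_A, l_B, l_C, l_N."""
    s = world.config.lattice_side
    lines = [f"#side\t{s}", f"#step\t{world.step_count}"]
    for i, j in zip(*np.nonzero(world.occ)):
        lines.append(
            f"{i * s + j}\t{world.lA[i, j]}\t{world.lB[i, j]}\t{world.lC[i, j]}\t{world.lN[i, j]}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_snapshot(path, config: ReplicatorWorldConfig) -> ReplicatorWorld:
    s = config.lattice_side
    world = ReplicatorWorld(
        config=config,
        occ=np.zeros((s, s), dtype=bool),
        lA=np.zeros((s, s), dtype=np.int64),
        lB=np.zeros((s, s), dtype=np.int64),
        lC=np.zeros((s, s), dtype=np.int64),
        lN=np.zeros((s, s), dtype=np.int64),
    )
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                if line.startswith("#step"):
                    world.step_count = int(line.split("\t")[1])
                continue
            site, a, b, c, n = map(int, line.split("\t"))
            i, j = divmod(site, s)
            world.occ[i, j] = True
            world.lA[i, j], world.lB[i, j], world.lC[i, j], world.lN[i, j] = a, b, c, n
    return world
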