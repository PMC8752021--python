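"""Deterministic random-stream derivation.

A single master seed drives an exploration run.  Every stochastic objective
evaluation receives its own independent child generator derived from the
master seed plus a structural key (round index, evaluation slot, replicate),
so a run is reproducible bit-for-bit while evaluations remain statistically
independent.  The derivation uses ``numpy.random.SeedSequence`` spawn keys,
which alternate-language ports can mirror structurally (round, slot,
replicate) even though the bit streams themselves are generator-specific.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]

_MASK = (1 << 31) - 1


def child_seed_sequence(seed: int, *key: int) -> np.random.SeedSequence:
    """Seed sequence for the child stream identified by ``key``."""
    return np.random.SeedSequence(int(seed) & _MASK, spawn_key=tuple(int(k) for k in key))


def child_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for the child stream identified by ``key``."""
    return np.random.Generator(np.random.PCG64(child_seed_sequence(seed, *key)))
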