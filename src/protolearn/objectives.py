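"""Scalar objective functions over testbed simulations.

An objective binds a testbed (the RNA-pool world, the replicator lattice, or
a closed-form synthetic surface) to a single number the explorer maximizes:
the NSR molecule count at a reference step, the NSR-minus-control difference
(the over-fitting control), the mean replicator length (with an ad-hoc
extinction fallback), or the synthetic surface value.  Objectives are plain
callables ``objective(params, rng) -> float`` and additionally expose
``parameter_defs`` so the explorer estimators can resolve the search space
from the objective alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import count
from typing import Sequence

import numpy as np

from .parameters import ParameterDef, ParameterSet
from . import nsr as _nsr
from . import replicator as _rep

__all__ = [
    "Inoculation",
    "ObjectiveSpec",
    "SyntheticObjective",
    "bundled_synthetic",
    "evaluate",
    "readout_nsr_count",
    "readout_ctrl_count",
    "readout_diff",
    "readout_mean_length",
    "synthetic_value",
]


@dataclass(frozen=True)
class Inoculation:
    """Scheduled introduction of molecules into an NSR world."""

    species: str  # "nsr" | "ctrl"
    copies: int
    step: int

    def __post_init__(self) -> None:
        if self.species not in ("nsr", "ctrl"):
            raise ValueError(f"unknown species {self.species!r}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.step < 0:
            raise ValueError("step must be >= 0")


def readout_nsr_count(world: "_nsr.NSRWorld") -> int:
    """Number of template strands carrying the NSR motif.

    Duplex-bound templates count (a strand busy templating its complement
    still exists); nascent strands never do.
    """
    return world.count_motif(world.config.nsr_motif)


def readout_ctrl_count(world: "_nsr.NSRWorld") -> int:
    """Number of template strands carrying the control motif."""
    return world.count_motif(world.config.ctrl_motif)


def readout_diff(world: "_nsr.NSRWorld") -> int:
    """NSR count minus control count (may be negative).

    Identity is judged by motif containment, so a knocked-out NSR still
    counts toward the NSR number — knockout removes function, not identity.
    """
    return readout_nsr_count(world) - readout_ctrl_count(world)


def readout_mean_length(world: "_rep.ReplicatorWorld", fallback: float) -> float:
    """Mean replicator length in monomers; ``fallback`` if the world is empty.

    The fallback convention marks "odd points": learning rounds whose
    simulation ends in extinction report the initial mean length instead of
    an undefined average.
    """
    lengths = world.lengths()
    if lengths.size == 0:
        return float(fallback)
    return float(lengths.mean())


_READOUTS = {"nsr_count", "nsr_minus_ctrl", "mean_replicator_length", "synthetic_value"}

#: process-wide stamp for per-evaluation trace files
_EVAL_COUNTER = count()


@dataclass(frozen=True)
class ObjectiveSpec:
    """Binds a testbed simulation to a scalar readout.

    Evaluation runs the named testbed from scratch to ``reference_step``
    (applying the inoculation schedule on the way), takes a single snapshot
    readout there, and averages over ``replicates`` independent runs on
    child streams spawned from the caller's generator.
    """

    testbed: str  # "nsr" | "replicator"
    readout: str
    reference_step: int
    world_config: object  # NSRWorldConfig | ReplicatorWorldConfig
    inoculations: tuple[Inoculation, ...] = ()
    extinction_fallback: float = 5.0
    replicates: int = 1
    objective_id: str = "objective"
    trace_dir: str | None = None

    def __post_init__(self) -> None:
        if self.testbed not in ("nsr", "replicator"):
            raise ValueError(f"unknown testbed {self.testbed!r}")
        if self.readout not in _READOUTS:
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.readout == "mean_replicator_length" and self.testbed != "replicator":
            raise ValueError("mean_replicator_length requires the replicator testbed")
        if self.testbed == "nsr" and self.readout not in ("nsr_count", "nsr_minus_ctrl"):
            raise ValueError(f"readout {self.readout!r} undefined for the nsr testbed")
        object.__setattr__(self, "inoculations", tuple(self.inoculations))
        if any(i.step > self.reference_step for i in self.inoculations):
            raise ValueError("inoculation scheduled after the reference step")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def parameter_defs(self) -> tuple[ParameterDef, ...]:
        if self.testbed == "nsr":
            return _nsr.parameter_defs()
        return _rep.parameter_defs()

    def _evaluate_once(self, params: ParameterSet, rng: np.random.Generator) -> float:
        record_every = (
            max(1, self.reference_step // 20) if self.trace_dir
            else max(1, self.reference_step)
        )
        if self.testbed == "nsr":
            sim_params = _nsr.NSRParams.from_parameter_set(params)
            world = _nsr.init_world(self.world_config)
            series = _nsr.run(
                world, sim_params, self.reference_step,
                inoculations=self.inoculations, rng=rng,
                record_every=record_every,
            )
            value = (
                float(readout_nsr_count(world))
                if self.readout == "nsr_count"
                else float(readout_diff(world))
            )
        else:
            sim_params = _rep.ReplicatorParams.from_parameter_set(params)
            world = _rep.init_world(self.world_config, rng)
            series = _rep.run(
                world, sim_params, self.reference_step, rng=rng,
                record_every=record_every,
                fallback=self.extinction_fallback,
            )
            value = readout_mean_length(world, self.extinction_fallback)
        if self.trace_dir:
            self._write_trace(series)
        return value

    def _write_trace(self, series) -> None:
        """Per-evaluation time series TSV (enabled by ``trace_dir``)."""
        from pathlib import Path

        out = Path(self.trace_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = next(_EVAL_COUNTER)
        series.to_csv(out / f"eval-{self.testbed}-{stamp:06d}.tsv", sep="\t", index=False)

    def __call__(self, params: ParameterSet, rng: np.random.Generator) -> float:
        if self.replicates == 1:
            return self._evaluate_once(params, rng)
        streams = rng.spawn(self.replicates)
        return float(
            np.mean([self._evaluate_once(params, s) for s in streams])
        )


@dataclass(frozen=True)
class SyntheticObjective:
    """Concave closed-form surface for validating the explorer.

    ``value = -sum_i w_i (ln p_i - ln p*_i)^2 + N(0, noise_sd)`` — the global
    maximum is 0 at the known optimum ``p*``, so recovery error is directly
    measurable.  The log-quadratic form matches the multiplicative geometry
    of the update rule without informing it.
    """

    parameter_defs: tuple[ParameterDef, ...]
    optimum: np.ndarray
    weights: np.ndarray
    noise_sd: float = 0.0
    objective_id: str = "synthetic"

    def __post_init__(self) -> None:
        opt = np.asarray(self.optimum, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if opt.shape != (len(self.parameter_defs),) or w.shape != opt.shape:
            raise ValueError("optimum/weights must match the parameter count")
        if np.any(opt <= 0) or np.any(w <= 0):
            raise ValueError("optimum and weights must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        opt.flags.writeable = False
        w.flags.writeable = False
        object.__setattr__(self, "optimum", opt)
        object.__setattr__(self, "weights", w)

    def __call__(self, params: ParameterSet, rng: np.random.Generator) -> float:
        v = params.values
        if np.any(v <= 0):
            raise ValueError("synthetic objective requires strictly positive parameters")
        value = -float(np.sum(self.weights * (np.log(v) - np.log(self.optimum)) ** 2))
        if self.noise_sd > 0:
            value += float(rng.normal(0.0, self.noise_sd))
        return value


def synthetic_value(
    obj: SyntheticObjective, params: ParameterSet, rng: np.random.Generator
) -> float:
    """Functional form of :meth:`SyntheticObjective.__call__`."""
    return obj(params, rng)


#: Fixed 8-dimensional validation surface: optima spread over four orders of
#: magnitude (like the learned probability sets) with uneven curvature.
_BUNDLED_OPTIMA = (0.3, 0.05, 0.4, 0.01, 0.2, 0.002, 0.5, 0.1)
_BUNDLED_WEIGHTS = (1.0, 0.5, 2.0, 1.0, 1.5, 0.7, 1.0, 1.2)
_BUNDLED_START_FACTORS = (2.5, 0.2, 0.5, 8.0, 0.15, 4.0, 0.3, 6.0)


def bundled_synthetic(noise_sd: float = 0.0) -> SyntheticObjective:
    """The bundled 8-parameter concave objective with a known optimum.

    Starting values sit within a factor of 10 of each optimum coordinate on
    both sides, so recovery exercises upward and downward learning at once.
    """
    defs = tuple(
        ParameterDef(
            name=f"q{i + 1}",
            initial=min(1.0, opt * fac),
            kind="probability",
            description="synthetic surface coordinate",
        )
        for i, (opt, fac) in enumerate(zip(_BUNDLED_OPTIMA, _BUNDLED_START_FACTORS))
    )
    return SyntheticObjective(
        parameter_defs=defs,
        optimum=np.array(_BUNDLED_OPTIMA),
        weights=np.array(_BUNDLED_WEIGHTS),
        noise_sd=noise_sd,
    )


def evaluate(spec, params: ParameterSet, rng: np.random.Generator) -> float:
    """Evaluate any objective (spec or callable) at ``params``."""
    return float(spec(params, rng))
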