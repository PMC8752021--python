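"""Automatic parameter exploration for stochastic simulators.

The central algorithm is a normalized finite-difference gradient ascent with
direction memory.  One learning round costs ``n + 1`` objective evaluations
for ``n`` parameters: a base evaluation ``O`` at the current parameter set,
and one evaluation per parameter with that parameter alone perturbed by the
learning rate ``e`` in its remembered test direction.  The resulting changes
``dO_i`` are normalized by the largest magnitude ``max_i |dO_i|`` and all
parameters are then updated simultaneously and multiplicatively:

    p_i  <-  p_i * (1 + e * g_i / max_abs)        (g_i >= 0)
    p_i  <-  p_i * (1 - e * |g_i| / max_abs)      (g_i < 0, additive form)
    p_i  <-  p_i / (1 + e * |g_i| / max_abs)      (g_i < 0, multiplicative form)

where ``g_i = s_i * dO_i`` is the measured slope with respect to *increasing*
``p_i`` (``s_i`` is the test direction).  The parameter with the largest
|change| moves by the full factor ``(1 + e)`` (or its downward form); every
other parameter moves in proportion to its potential.  The next round's test
direction for each parameter is the direction it actually moved.

Two further strategies share the same evaluation contract:

* coordinate ascent — per parameter, a greedy argmax over seven geometric
  candidates ``p*(1+e)^k`` and ``p*(1-e)^k`` (k = 0..3), installed one
  parameter at a time;
* progressive learning — a schedule of gradient-ascent stages against
  objectives at successively later simulation steps, each stage warm-started
  from the previous stage's final parameters and direction memory.

An objective is any callable ``objective(params: ParameterSet, rng) -> float``
that returns a finite number for in-bounds parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._rng import child_rng
from .parameters import ParameterDef, ParameterSet, clamp

__all__ = [
    "ExplorationError",
    "LearningConfig",
    "DeltaVector",
    "RoundRecord",
    "LearningTrace",
    "probe",
    "gradient_update",
    "next_directions",
    "coordinate_candidates",
    "run_gradient_ascent",
    "run_coordinate_ascent",
    "run_progressive",
    "GradientAscentExplorer",
    "CoordinateAscentExplorer",
    "ProgressiveExplorer",
]

Objective = Callable[[ParameterSet, np.random.Generator], float]


class ExplorationError(RuntimeError):
    """A learning run aborted (non-finite objective or corrupted update)."""


@dataclass(frozen=True)
class LearningConfig:
    """Settings shared by all exploration strategies.

    ``learning_rate`` plays a double role: it is both the testing rate used
    to estimate the finite-difference gradient and the veritable learning
    rate scaling the update step.  The two are kept equal deliberately — a
    testing rate much smaller than the learning rate wastes simulations on
    gradient precision the step does not need, and vice versa.
    """

    learning_rate: float = 0.2
    rounds: int = 100
    strategy: str = "gradient"  # "gradient" | "coordinate"
    zero_change_direction: str = "up"  # probe direction after a zero change
    step_form: str = "additive"  # downward form: additive p*(1-e) | multiplicative p/(1+e)
    replicates_per_evaluation: int = 1
    seed: int = 0
    direction: str = "ascent"  # "ascent" | "descent"
    common_random_numbers: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate < 1.0):
            raise ValueError(f"learning_rate must be in (0,1), got {self.learning_rate}")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.strategy not in ("gradient", "coordinate"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.zero_change_direction not in ("up", "down"):
            raise ValueError(f"unknown zero_change_direction {self.zero_change_direction!r}")
        if self.step_form not in ("additive", "multiplicative"):
            raise ValueError(f"unknown step_form {self.step_form!r}")
        if self.replicates_per_evaluation < 1:
            raise ValueError("replicates_per_evaluation must be >= 1")
        if self.direction not in ("ascent", "descent"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class DeltaVector:
    """Finite-difference probe result for one learning round."""

    base_objective: float
    deltas: np.ndarray  # dO_i = O_i - O, one per parameter
    test_directions: np.ndarray  # s_i in {+1, -1}
    max_abs: float  # max_i |dO_i|

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", np.asarray(self.deltas, dtype=float))
        object.__setattr__(self, "test_directions", np.asarray(self.test_directions, dtype=int))
        if self.deltas.shape != self.test_directions.shape:
            raise ValueError("deltas and test_directions differ in length")

    @property
    def slopes(self) -> np.ndarray:
        """g_i = s_i * dO_i, the slope w.r.t. increasing p_i."""
        return self.test_directions * self.deltas


@dataclass(frozen=True)
class RoundRecord:
    round_index: int
    base_objective: float
    delta: DeltaVector
    params_after: ParameterSet
    evaluations_used: int


@dataclass(frozen=True)
class LearningTrace:
    """Per-round history of one exploration run."""

    config: LearningConfig
    objective_id: str
    records: tuple[RoundRecord, ...]
    stage_boundaries: tuple[int, ...] = ()

    @property
    def final_params(self) -> ParameterSet:
        return self.records[-1].params_after

    @property
    def final_objective(self) -> float:
        return self.records[-1].base_objective

    def to_frame(self):
        """Tabular view: one row per round (round, objective, parameters)."""
        import pandas as pd

        names = self.records[0].params_after.names
        rows = [
            {
                "round": r.round_index,
                "objective": r.base_objective,
                **{n: v for n, v in zip(names, r.params_after.values)},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation plumbing


def _evaluate(
    objective: Objective,
    params: ParameterSet,
    *,
    seed: int,
    round_index: int,
    slot: int,
    replicates: int,
    common_random_numbers: bool,
    sign: float,
    what: str,
) -> float:
    """One (replicate-averaged) objective evaluation on its own child streams."""
    key_slot = 0 if common_random_numbers else slot
    total = 0.0
    for rep in range(replicates):
        rng = child_rng(seed, round_index, key_slot, rep)
        total += float(objective(params, rng))
    value = sign * total / replicates
    if not math.isfinite(value):
        raise ExplorationError(
            f"non-finite objective {value!r} at round {round_index}, {what}"
        )
    return value


def _perturb(value: float, e: float, direction: int, step_form: str, pdef: ParameterDef) -> float:
    """Single-parameter probe value in the given test direction, clamped."""
    if direction >= 0:
        cand = value * (1.0 + e)
    elif step_form == "additive":
        cand = value * (1.0 - e)
    else:
        cand = value / (1.0 + e)
    return clamp(cand, pdef)


def probe(
    objective: Objective,
    params: ParameterSet,
    e: float,
    directions: Sequence[int] | np.ndarray,
    *,
    step_form: str = "additive",
    seed: int = 0,
    round_index: int = 1,
    replicates: int = 1,
    common_random_numbers: bool = False,
    sign: float = 1.0,
) -> DeltaVector:
    """Measure the per-parameter objective changes for one learning round.

    Evaluation slot 0 is the base run; slot ``i + 1`` perturbs parameter
    ``i`` alone by the learning rate in its remembered test direction.
    """
    directions = np.asarray(directions, dtype=int)
    n = len(params)
    if directions.shape != (n,):
        raise ValueError("one test direction per parameter required")
    base = _evaluate(
        objective, params, seed=seed, round_index=round_index, slot=0,
        replicates=replicates, common_random_numbers=common_random_numbers,
        sign=sign, what="base evaluation",
    )
    deltas = np.empty(n, dtype=float)
    for i in range(n):
        cand_value = _perturb(float(params.values[i]), e, int(directions[i]), step_form, params.defs[i])
        cand = params.with_value(i, cand_value)
        o_i = _evaluate(
            objective, cand, seed=seed, round_index=round_index, slot=i + 1,
            replicates=replicates, common_random_numbers=common_random_numbers,
            sign=sign, what=f"candidate for parameter {params.defs[i].name!r}",
        )
        deltas[i] = o_i - base
    return DeltaVector(
        base_objective=base,
        deltas=deltas,
        test_directions=directions,
        max_abs=float(np.max(np.abs(deltas))) if n else 0.0,
    )


def gradient_update(
    params: ParameterSet,
    delta: DeltaVector,
    e: float,
    step_form: str = "additive",
) -> ParameterSet:
    """Simultaneous normalized multiplicative update of all parameters.

    The parameter attaining ``max_abs`` moves by exactly the full factor;
    a zero total gradient (``max_abs == 0``) skips the update entirely.
    """
    max_abs = delta.max_abs
    if not math.isfinite(max_abs):
        raise ExplorationError(f"non-finite max_abs {max_abs!r}")
    if max_abs == 0.0:
        return params
    g = delta.slopes
    scale = e * np.abs(g) / max_abs
    vals = params.values.copy()
    up = g >= 0
    vals[up] = vals[up] * (1.0 + scale[up])
    if step_form == "additive":
        vals[~up] = vals[~up] * (1.0 - scale[~up])
    else:
        vals[~up] = vals[~up] / (1.0 + scale[~up])
    vals = np.array([clamp(float(v), d) for v, d in zip(vals, params.defs)])
    return params.with_values(vals)


def next_directions(delta: DeltaVector, zero_change_direction: str = "up") -> np.ndarray:
    """Test directions for the next round: the way each parameter just moved.

    A parameter whose probe left the objective unchanged is probed upward
    next round by default, or downward when ``zero_change_direction="down"``.
    """
    g = delta.slopes
    tie = 1 if zero_change_direction == "up" else -1
    out = np.where(g > 0, 1, np.where(g < 0, -1, tie))
    return out.astype(int)


# ---------------------------------------------------------------------------
# strategies


def run_gradient_ascent(
    objective: Objective,
    defs: Sequence[ParameterDef],
    config: LearningConfig,
    *,
    initial: ParameterSet | None = None,
    initial_directions: np.ndarray | None = None,
    round_offset: int = 0,
    objective_id: str = "objective",
) -> LearningTrace:
    """Run ``config.rounds`` rounds of normalized gradient ascent.

    ``direction="descent"`` negates the objective before every comparison, so
    the recorded objective values are those of the maximized (signed) form.
    ``round_offset`` shifts the seeding key, letting progressive stages share
    a master seed without stream reuse.
    """
    if config.strategy != "gradient":
        raise ValueError("config.strategy must be 'gradient'")
    defs = tuple(defs)
    params = initial if initial is not None else ParameterSet.from_defs(defs)
    n = len(params)
    directions = (
        np.ones(n, dtype=int)
        if initial_directions is None
        else np.asarray(initial_directions, dtype=int).copy()
    )
    sign = 1.0 if config.direction == "ascent" else -1.0
    records: list[RoundRecord] = []
    for r in range(1, config.rounds + 1):
        round_index = round_offset + r
        try:
            delta = probe(
                objective, params, config.learning_rate, directions,
                step_form=config.step_form, seed=config.seed,
                round_index=round_index,
                replicates=config.replicates_per_evaluation,
                common_random_numbers=config.common_random_numbers,
                sign=sign,
            )
            params = gradient_update(params, delta, config.learning_rate, config.step_form)
        except ExplorationError as err:
            raise ExplorationError(f"round {round_index}: {err}") from err
        directions = next_directions(delta, config.zero_change_direction)
        records.append(
            RoundRecord(
                round_index=round_index,
                base_objective=delta.base_objective,
                delta=delta,
                params_after=params,
                evaluations_used=n + 1,
            )
        )
    return LearningTrace(config=config, objective_id=objective_id, records=tuple(records))


def coordinate_candidates(p: float, e: float, pdef: ParameterDef) -> list[float]:
    """Seven geometric candidates around ``p``, in-bounds ones only.

    Fixed order: the current value, three upward values ``p*(1+e)^k`` and
    three downward values ``p*(1-e)^k`` (k = 1..3).  Out-of-bounds candidates
    are dropped, not clamped; the current value always survives.
    """
    if not (0.0 < e < 1.0):
        raise ValueError("learning rate must be in (0,1)")
    raw = [p]
    raw += [p * (1.0 + e) ** k for k in (1, 2, 3)]
    raw += [p * (1.0 - e) ** k for k in (1, 2, 3)]
    return [c for c in raw if pdef.lower <= c <= pdef.upper]


def run_coordinate_ascent(
    objective: Objective,
    defs: Sequence[ParameterDef],
    config: LearningConfig,
    *,
    initial: ParameterSet | None = None,
    objective_id: str = "objective",
) -> LearningTrace:
    """Greedy per-parameter candidate search, one parameter at a time.

    Within a round, parameters are visited in their fixed order; for each the
    incumbent and its surviving geometric candidates are all evaluated on
    fresh child streams and the argmax is installed before the next visit.
    The incumbent is re-evaluated at every visit because the objective is
    stochastic and a stale cached value would bias the argmax.  Ties break in
    favor of the incumbent, then the earlier candidate.
    """
    if config.strategy != "coordinate":
        raise ValueError("config.strategy must be 'coordinate'")
    defs = tuple(defs)
    params = initial if initial is not None else ParameterSet.from_defs(defs)
    n = len(params)
    sign = 1.0 if config.direction == "ascent" else -1.0
    e = config.learning_rate
    records: list[RoundRecord] = []
    for r in range(1, config.rounds + 1):
        evaluations = 0
        base_first: float | None = None
        deltas = np.zeros(n)
        dirs = np.ones(n, dtype=int)
        slot = 0
        for i in range(n):
            p_cur = float(params.values[i])
            cands = coordinate_candidates(p_cur, e, params.defs[i])
            values = []
            for cand in cands:
                cand_params = params if cand == p_cur else params.with_value(i, cand)
                try:
                    v = _evaluate(
                        objective, cand_params, seed=config.seed, round_index=r,
                        slot=slot, replicates=config.replicates_per_evaluation,
                        common_random_numbers=config.common_random_numbers,
                        sign=sign,
                        what=f"candidate {cand:g} for parameter {params.defs[i].name!r}",
                    )
                except ExplorationError as err:
                    raise ExplorationError(f"round {r}: {err}") from err
                values.append(v)
                slot += 1
                evaluations += 1
            if base_first is None:
                base_first = values[0]
            # argmax with ties to the incumbent (index 0), then earlier index
            best = max(range(len(cands)), key=lambda j: (values[j], -j))
            if values[best] == values[0]:
                best = 0
            if best != 0:
                params = params.with_value(i, cands[best])
            deltas[i] = values[best] - values[0]
            dirs[i] = 1 if cands[best] >= p_cur else -1
        delta = DeltaVector(
            base_objective=float(base_first),
            deltas=deltas,
            test_directions=dirs,
            max_abs=float(np.max(np.abs(deltas))) if n else 0.0,
        )
        records.append(
            RoundRecord(
                round_index=r,
                base_objective=float(base_first),
                delta=delta,
                params_after=params,
                evaluations_used=evaluations,
            )
        )
    return LearningTrace(config=config, objective_id=objective_id, records=tuple(records))


def run_progressive(
    objective_schedule: Sequence[tuple[Objective, int]],
    defs: Sequence[ParameterDef],
    config: LearningConfig,
    *,
    initial: ParameterSet | None = None,
    objective_id: str = "progressive",
) -> LearningTrace:
    """Staged gradient ascent with warm starts (a transfer-learning schedule).

    Each ``(objective, rounds)`` stage runs gradient ascent seeded with the
    previous stage's final parameters *and* direction memory; the trace
    concatenates all stages and records the stage boundaries.
    """
    if not objective_schedule:
        raise ValueError("objective_schedule must be non-empty")
    defs = tuple(defs)
    params = initial if initial is not None else ParameterSet.from_defs(defs)
    directions = np.ones(len(params), dtype=int)
    records: list[RoundRecord] = []
    boundaries: list[int] = []
    offset = 0
    for stage_idx, (stage_objective, stage_rounds) in enumerate(objective_schedule):
        stage_config = replace(config, rounds=int(stage_rounds))
        trace = run_gradient_ascent(
            stage_objective, defs, stage_config,
            initial=params, initial_directions=directions,
            round_offset=offset, objective_id=f"{objective_id}[{stage_idx}]",
        )
        records.extend(trace.records)
        params = trace.final_params
        directions = next_directions(trace.records[-1].delta, config.zero_change_direction)
        offset += stage_rounds
        boundaries.append(offset)
    return LearningTrace(
        config=config,
        objective_id=objective_id,
        records=tuple(records),
        stage_boundaries=tuple(boundaries[:-1]),
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator facade


class _BaseExplorer(BaseEstimator):
    """Shared fit plumbing for the explorer estimators."""

    def _learning_config(self, strategy: str) -> LearningConfig:
        return LearningConfig(
            learning_rate=self.learning_rate,
            rounds=self.rounds,
            strategy=strategy,
            zero_change_direction=self.zero_change_direction,
            step_form=self.step_form,
            replicates_per_evaluation=self.replicates_per_evaluation,
            seed=self.seed,
            direction=self.direction,
            common_random_numbers=self.common_random_numbers,
        )

    @staticmethod
    def _resolve_defs(objective, defs):
        if defs is not None:
            return tuple(defs)
        got = getattr(objective, "parameter_defs", None)
        if got is None:
            raise ValueError(
                "pass parameter definitions explicitly or use an objective "
                "exposing .parameter_defs"
            )
        return tuple(got)

    def _finish(self, trace: LearningTrace):
        self.trace_ = trace
        self.params_ = trace.final_params
        self.best_params_ = trace.final_params.as_dict()
        self.objective_value_ = trace.final_objective
        self.n_evaluations_ = sum(r.evaluations_used for r in trace.records)
        return self


class GradientAscentExplorer(_BaseExplorer):
    """Normalized finite-difference gradient ascent over simulator parameters.

    A search estimator in the spirit of sklearn's ``SearchCV`` classes:
    ``fit`` consumes an objective (a callable ``objective(params, rng) ->
    float`` or a bound :class:`protolearn.objectives.ObjectiveSpec`) and
    exposes the learned parameters and the full learning trace as fitted
    attributes.

    Parameters
    ----------
    learning_rate
        Fractional perturbation ``e`` in (0, 1); both testing and update rate.
    rounds
        Number of learning rounds (each costs ``n + 1`` evaluations).
    step_form
        Downward adjustment form: ``"additive"`` (``p*(1-e)``) or
        ``"multiplicative"`` (``p/(1+e)``).
    zero_change_direction
        Probe direction taken after a zero objective change: ``"up"``/``"down"``.
    direction
        ``"ascent"`` maximizes the objective, ``"descent"`` minimizes it.
    replicates_per_evaluation
        Independent simulations averaged per objective evaluation.
    common_random_numbers
        Reuse one random stream for all evaluations of a round (variance
        reduction switch; off by default).
    seed
        Master seed for all child evaluation streams.

    Attributes
    ----------
    trace_ : LearningTrace
    params_ : ParameterSet
    best_params_ : dict
    objective_value_ : float
    n_evaluations_ : int

    Examples
    --------
    >>> from protolearn.objectives import bundled_synthetic
    >>> obj = bundled_synthetic()
    >>> exp = GradientAscentExplorer(learning_rate=0.2, rounds=50, seed=1).fit(obj)
    >>> exp.objective_value_ <= 0.0
    True
    """

    def __init__(
        self,
        learning_rate: float = 0.2,
        rounds: int = 100,
        *,
        step_form: str = "additive",
        zero_change_direction: str = "up",
        direction: str = "ascent",
        replicates_per_evaluation: int = 1,
        common_random_numbers: bool = False,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.rounds = rounds
        self.step_form = step_form
        self.zero_change_direction = zero_change_direction
        self.direction = direction
        self.replicates_per_evaluation = replicates_per_evaluation
        self.common_random_numbers = common_random_numbers
        self.seed = seed

    def fit(self, objective, defs=None, initial: ParameterSet | None = None):
        defs = self._resolve_defs(objective, defs)
        trace = run_gradient_ascent(
            objective, defs, self._learning_config("gradient"), initial=initial,
            objective_id=getattr(objective, "objective_id", "objective"),
        )
        return self._finish(trace)


class CoordinateAscentExplorer(_BaseExplorer):
    """Greedy per-parameter candidate search (coordinate ascent).

    Shares the constructor and fitted attributes of
    :class:`GradientAscentExplorer`; per round it visits the parameters in
    order and installs, for each, the best of up to seven geometric
    candidates before moving on.
    """

    def __init__(
        self,
        learning_rate: float = 0.2,
        rounds: int = 100,
        *,
        step_form: str = "additive",
        zero_change_direction: str = "up",
        direction: str = "ascent",
        replicates_per_evaluation: int = 1,
        common_random_numbers: bool = False,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.rounds = rounds
        self.step_form = step_form
        self.zero_change_direction = zero_change_direction
        self.direction = direction
        self.replicates_per_evaluation = replicates_per_evaluation
        self.common_random_numbers = common_random_numbers
        self.seed = seed

    def fit(self, objective, defs=None, initial: ParameterSet | None = None):
        defs = self._resolve_defs(objective, defs)
        trace = run_coordinate_ascent(
            objective, defs, self._learning_config("coordinate"), initial=initial,
            objective_id=getattr(objective, "objective_id", "objective"),
        )
        return self._finish(trace)


class ProgressiveExplorer(_BaseExplorer):
    """Staged gradient ascent against a schedule of objectives.

    ``fit`` takes the schedule — an ordered sequence of ``(objective,
    rounds)`` pairs — and runs each stage warm-started from the previous
    stage's final parameters and direction memory.  The constructor's
    ``rounds`` is ignored (stage lengths come from the schedule).
    """

    def __init__(
        self,
        learning_rate: float = 0.2,
        *,
        step_form: str = "additive",
        zero_change_direction: str = "up",
        direction: str = "ascent",
        replicates_per_evaluation: int = 1,
        common_random_numbers: bool = False,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.step_form = step_form
        self.zero_change_direction = zero_change_direction
        self.direction = direction
        self.replicates_per_evaluation = replicates_per_evaluation
        self.common_random_numbers = common_random_numbers
        self.seed = seed

    def fit(self, schedule, defs=None, initial: ParameterSet | None = None):
        schedule = list(schedule)
        if defs is None and schedule:
            defs = getattr(schedule[0][0], "parameter_defs", None)
        if defs is None:
            raise ValueError("parameter definitions required")
        config = LearningConfig(
            learning_rate=self.learning_rate,
            rounds=1,  # per-stage rounds come from the schedule
            strategy="gradient",
            zero_change_direction=self.zero_change_direction,
            step_form=self.step_form,
            replicates_per_evaluation=self.replicates_per_evaluation,
            seed=self.seed,
            direction=self.direction,
            common_random_numbers=self.common_random_numbers,
        )
        trace = run_progressive(schedule, tuple(defs), config, initial=initial)
        self.stage_boundaries_ = trace.stage_boundaries
        return self._finish(trace)
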