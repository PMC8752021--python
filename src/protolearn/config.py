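"""Experiment configuration: schema, validation, YAML round-trip.

A single YAML (or JSON) document describes one experiment: the explorable
parameters with their starting values, the learning settings, the objective
(or a schedule of objectives for progressive runs) and the testbed world
constants.  The schema is strict — unknown keys are rejected with
field-level messages — and round-trips losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import nsr as _nsr
from . import replicator as _rep
from .explore import LearningConfig
from .objectives import Inoculation, ObjectiveSpec, SyntheticObjective
from .parameters import ParameterDef, ParameterSet

__all__ = [
    "ExperimentConfig",
    "load_config",
    "save_config",
    "config_hash",
    "bundled_config",
    "BUNDLED_CONFIGS",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParameterModel(_Strict):
    name: str
    initial: float
    kind: Literal["probability", "positive"] = "probability"
    lower: Optional[float] = None
    upper: Optional[float] = None
    description: str = ""

    def to_def(self) -> ParameterDef:
        return ParameterDef(
            name=self.name, initial=self.initial, kind=self.kind,
            lower=self.lower, upper=self.upper, description=self.description,
        )


class LearningModel(_Strict):
    rate: float = 0.2
    rounds: int = 100
    strategy: Literal["gradient", "coordinate"] = "gradient"
    zero_change_direction: Literal["up", "down"] = "up"
    step_form: Literal["additive", "multiplicative"] = "additive"
    replicates: int = 1
    direction: Literal["ascent", "descent"] = "ascent"
    common_random_numbers: bool = False


class InoculationModel(_Strict):
    species: Literal["nsr", "ctrl"]
    copies: int = Field(ge=1)
    step: int = Field(ge=0)


class NSRWorldModel(_Strict):
    grid_side: int = 30
    total_material: int = 40_000
    nsr_motif: str = "AUGCCGUAAC"
    ctrl_motif: str = "GACUUAGCAU"
    duplex_separation: float = 0.5
    end_decay: float = 0.001
    knockout: bool = False

    def to_config(self, seed: int = 0) -> _nsr.NSRWorldConfig:
        return _nsr.NSRWorldConfig(
            grid_side=self.grid_side, total_material=self.total_material,
            nsr_motif=self.nsr_motif, ctrl_motif=self.ctrl_motif,
            duplex_separation=self.duplex_separation, end_decay=self.end_decay,
            knockout=self.knockout, seed=seed,
        )


class ReplicatorWorldModel(_Strict):
    lattice_side: int = 100
    initial_occupancy: float = 0.3
    initial_length: int = 5
    decay_prob: float = 0.1
    dispersal_prob: float = 0.05
    base_error: float = 0.05
    indel_fraction: float = 0.2
    claim_scale: float = 2.0
    claim_length_scale: float = 400.0

    def to_config(self, seed: int = 0) -> _rep.ReplicatorWorldConfig:
        return _rep.ReplicatorWorldConfig(
            lattice_side=self.lattice_side,
            initial_occupancy=self.initial_occupancy,
            initial_length=self.initial_length,
            decay_prob=self.decay_prob,
            dispersal_prob=self.dispersal_prob,
            base_error=self.base_error,
            indel_fraction=self.indel_fraction,
            claim_scale=self.claim_scale,
            claim_length_scale=self.claim_length_scale,
            seed=seed,
        )


class SyntheticModel(_Strict):
    optimum: list[float]
    weights: list[float]
    noise_sd: float = 0.0


class ObjectiveModel(_Strict):
    testbed: Literal["nsr", "replicator", "synthetic"]
    readout: Literal[
        "nsr_count", "nsr_minus_ctrl", "mean_replicator_length", "synthetic_value"
    ]
    reference_step: int = 0
    inoculations: list[InoculationModel] = Field(default_factory=list)
    extinction_fallback: float = 5.0
    replicates: int = 1
    rounds: Optional[int] = None  # stage length inside a progressive schedule
    trace: bool = False  # write per-evaluation time-series TSVs
    synthetic: Optional[SyntheticModel] = None

    @model_validator(mode="after")
    def _check(self):
        if self.testbed == "synthetic":
            if self.readout != "synthetic_value" or self.synthetic is None:
                raise ValueError(
                    "synthetic testbed requires readout synthetic_value and a "
                    "'synthetic' section"
                )
        else:
            if self.readout == "synthetic_value":
                raise ValueError("synthetic_value readout requires the synthetic testbed")
            if self.reference_step < 1:
                raise ValueError("reference_step must be >= 1 for simulator objectives")
        for ino in self.inoculations:
            if ino.step > self.reference_step:
                raise ValueError(
                    f"inoculation at step {ino.step} after reference step {self.reference_step}"
                )
        return self


_TESTBED_PARAMS = {
    "nsr": _nsr.PARAM_NAMES,
    "replicator": _rep.PARAM_NAMES,
}


class ExperimentConfig(_Strict):
    """Top-level experiment description (see module docstring)."""

    seed: int = 0
    output_dir: str = "results"
    record_every: int = 1000
    parameters: list[ParameterModel]
    learning: LearningModel = Field(default_factory=LearningModel)
    objective: Optional[ObjectiveModel] = None
    objective_schedule: Optional[list[ObjectiveModel]] = None
    nsr_world: Optional[NSRWorldModel] = None
    replicator_world: Optional[ReplicatorWorldModel] = None

    @model_validator(mode="after")
    def _check(self):
        if (self.objective is None) == (self.objective_schedule is None):
            raise ValueError("exactly one of 'objective' / 'objective_schedule' required")
        if self.objective_schedule is not None:
            if not self.objective_schedule:
                raise ValueError("objective_schedule must be non-empty")
            testbeds = {o.testbed for o in self.objective_schedule}
            if len(testbeds) > 1:
                raise ValueError("all schedule stages must use the same testbed")
            for o in self.objective_schedule:
                if o.rounds is None or o.rounds < 1:
                    raise ValueError("every schedule stage needs rounds >= 1")
        testbed = self._testbed()
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        required = _TESTBED_PARAMS.get(testbed)
        if required is not None:
            missing = set(required) - set(names)
            extra = set(names) - set(required)
            if missing or extra:
                raise ValueError(
                    f"{testbed} testbed requires exactly parameters {list(required)}; "
                    f"missing {sorted(missing)}, unexpected {sorted(extra)}"
                )
            world_field = "nsr_world" if testbed == "nsr" else "replicator_world"
            if getattr(self, world_field) is None:
                raise ValueError(f"{testbed} testbed requires a '{world_field}' section")
        if testbed == "synthetic":
            for o in self._objectives():
                n = len(self.parameters)
                if len(o.synthetic.optimum) != n or len(o.synthetic.weights) != n:
                    raise ValueError(
                        "synthetic optimum/weights must match the parameter count"
                    )
        return self

    # -- builders -----------------------------------------------------------

    def _objectives(self) -> list[ObjectiveModel]:
        if self.objective is not None:
            return [self.objective]
        return list(self.objective_schedule)

    def _testbed(self) -> str:
        return (self.objective or self.objective_schedule[0]).testbed

    def parameter_defs(self) -> tuple[ParameterDef, ...]:
        return tuple(p.to_def() for p in self.parameters)

    def initial_params(self) -> ParameterSet:
        return ParameterSet.from_defs(self.parameter_defs())

    def learning_config(self) -> LearningConfig:
        lm = self.learning
        return LearningConfig(
            learning_rate=lm.rate, rounds=lm.rounds, strategy=lm.strategy,
            zero_change_direction=lm.zero_change_direction, step_form=lm.step_form,
            replicates_per_evaluation=lm.replicates, seed=self.seed,
            direction=lm.direction, common_random_numbers=lm.common_random_numbers,
        )

    def build_objective(self, model: ObjectiveModel | None = None):
        """Materialize one objective (callable) from its model."""
        model = model or self.objective
        if model.testbed == "synthetic":
            syn = model.synthetic
            import numpy as np

            return SyntheticObjective(
                parameter_defs=self.parameter_defs(),
                optimum=np.asarray(syn.optimum),
                weights=np.asarray(syn.weights),
                noise_sd=syn.noise_sd,
            )
        if model.testbed == "nsr":
            world_config = self.nsr_world.to_config(self.seed)
        else:
            world_config = self.replicator_world.to_config(self.seed)
        return ObjectiveSpec(
            testbed=model.testbed,
            readout=model.readout,
            reference_step=model.reference_step,
            world_config=world_config,
            inoculations=tuple(
                Inoculation(i.species, i.copies, i.step) for i in model.inoculations
            ),
            extinction_fallback=model.extinction_fallback,
            replicates=model.replicates,
            objective_id=f"{model.testbed}:{model.readout}@{model.reference_step}",
            trace_dir=f"{self.output_dir}/eval-traces" if model.trace else None,
        )

    def build_schedule(self):
        """[(objective, rounds), ...] for progressive runs."""
        return [(self.build_objective(o), o.rounds) for o in self.objective_schedule]


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML/JSON experiment file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return ExperimentConfig.model_validate(data)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(exclude_none=True), sort_keys=False)
    )


def config_hash(config: ExperimentConfig) -> str:
    """Stable SHA-256 of the canonical JSON form (provenance tag)."""
    canon = json.dumps(config.model_dump(exclude_none=True), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


#: Names of the configuration files shipped with the package.
BUNDLED_CONFIGS = (
    "nsr-fig1",
    "nsr-learn",
    "nsr-diff-fig5",
    "replicator-fig7",
    "replicator-fig8a",
    "replicator-fig8c",
    "progressive-s3",
    "synthetic",
    "nsr-learn-small",
    "nsr-diff-small",
    "replicator-learn-small",
    "progressive-small",
)


def bundled_config(name: str) -> ExperimentConfig:
    """Load one of the named reference configurations shipped in the package."""
    from importlib import resources

    if name not in BUNDLED_CONFIGS:
        raise KeyError(f"unknown bundled config {name!r}; choose from {BUNDLED_CONFIGS}")
    ref = resources.files("protolearn").joinpath("data", f"{name}.yaml")
    data = yaml.safe_load(ref.read_text())
    return ExperimentConfig.model_validate(data)
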