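"""Explorable parameter definitions and bounded multiplicative updates.

Every exploration strategy in :mod:`protolearn.explore` perturbs parameters
multiplicatively (``p * (1 + e)`` and its downward forms), so an exact zero is
absorbing.  Probability-kind parameters therefore live on ``[1e-12, 1]`` and
generic positive reals on ``[1e-12, 1e6]``; updates that leave the box are
clamped to the nearest bound (with a :class:`ClampWarning`) rather than
rejected, which preserves the simultaneous-update semantics of a learning
round.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "PROBABILITY_BOUNDS",
    "POSITIVE_BOUNDS",
    "ClampWarning",
    "ParameterDef",
    "ParameterSet",
    "clamp",
]

#: Default bounds for probability-kind parameters.  The lower bound is
#: strictly positive so multiplicative updates can recover from near-zero.
PROBABILITY_BOUNDS = (1e-12, 1.0)

#: Default bounds for positive-real parameters (e.g. replicator activity
#: coefficients).
POSITIVE_BOUNDS = (1e-12, 1e6)


class ClampWarning(UserWarning):
    """Raised (as a warning) when a parameter update hits a bound."""


@dataclass(frozen=True)
class ParameterDef:
    """Definition of one explorable parameter.

    Parameters
    ----------
    name
        Identifier, unique within a parameter collection.
    initial
        Starting value; must lie within ``[lower, upper]``.
    kind
        ``"probability"`` (bounded above by 1) or ``"positive"``.
    lower, upper
        Value bounds.  When omitted they default from ``kind``.
    description
        Free-text description of the mechanism the parameter controls.
    """

    name: str
    initial: float
    kind: str = "probability"
    lower: float | None = None
    upper: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("probability", "positive"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        default = PROBABILITY_BOUNDS if self.kind == "probability" else POSITIVE_BOUNDS
        if self.lower is None:
            object.__setattr__(self, "lower", default[0])
        if self.upper is None:
            object.__setattr__(self, "upper", default[1])
        if not (self.lower >= 0 and self.lower < self.upper):
            raise ValueError(
                f"{self.name}: require 0 <= lower < upper, got [{self.lower}, {self.upper}]"
            )
        if self.kind == "probability" and self.upper > 1.0:
            raise ValueError(f"{self.name}: probability upper bound {self.upper} > 1")
        if not (self.lower <= self.initial <= self.upper):
            raise ValueError(
                f"{self.name}: initial {self.initial} outside [{self.lower}, {self.upper}]"
            )


def clamp(value: float, pdef: ParameterDef) -> float:
    """Clamp ``value`` into ``pdef``'s bounds, warning when a bound fires.

    Idempotent for any finite input.  Non-finite values indicate a corrupted
    update upstream and raise ``ValueError``.
    """
    if not math.isfinite(value):
        raise ValueError(f"{pdef.name}: non-finite value {value!r} in update")
    if value < pdef.lower:
        warnings.warn(
            f"{pdef.name}: clamped {value:g} to lower bound {pdef.lower:g}",
            ClampWarning,
            stacklevel=2,
        )
        return pdef.lower
    if value > pdef.upper:
        warnings.warn(
            f"{pdef.name}: clamped {value:g} to upper bound {pdef.upper:g}",
            ClampWarning,
            stacklevel=2,
        )
        return pdef.upper
    return value


@dataclass(frozen=True)
class ParameterSet:
    """Ordered, named collection of parameter values under exploration.

    The iteration order of ``defs`` is fixed and shared by every learning
    round: index ``i`` in the exploration formulas always refers to this
    order.
    """

    defs: tuple[ParameterDef, ...]
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len({d.name for d in self.defs}) != len(self.defs):
            raise ValueError("duplicate parameter names")
        if self.values is None:
            vals = np.array([d.initial for d in self.defs], dtype=float)
        else:
            vals = np.asarray(self.values, dtype=float).copy()
        if vals.shape != (len(self.defs),):
            raise ValueError(
                f"expected {len(self.defs)} values, got shape {vals.shape}"
            )
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)
        for d, v in zip(self.defs, vals):
            if not (d.lower <= v <= d.upper):
                raise ValueError(f"{d.name}: value {v} outside [{d.lower}, {d.upper}]")

    @classmethod
    def from_defs(cls, defs: Sequence[ParameterDef]) -> "ParameterSet":
        """Build a set at every definition's initial value."""
        return cls(defs=tuple(defs))

    @classmethod
    def from_mapping(
        cls, defs: Sequence[ParameterDef], values: Mapping[str, float]
    ) -> "ParameterSet":
        return cls(
            defs=tuple(defs),
            values=np.array([values[d.name] for d in defs], dtype=float),
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.defs)

    def __len__(self) -> int:
        return len(self.defs)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {d.name: float(v) for d, v in zip(self.defs, self.values)}

    def with_values(self, values: np.ndarray | Sequence[float]) -> "ParameterSet":
        """Same definitions, new (already clamped) values."""
        return ParameterSet(defs=self.defs, values=np.asarray(values, dtype=float))

    def with_value(self, index: int, value: float) -> "ParameterSet":
        vals = self.values.copy()
        vals[index] = value
        return self.with_values(vals)
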