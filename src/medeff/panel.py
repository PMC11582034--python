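"""Panel data model: variables, drug profiles and the benchmark set.

A benchmark set (:class:`Panel`) couples a :class:`VariableSchema` — which
declares each variable's role in the efficiency model — with an ordered
collection of :class:`UnitProfile` rows, one per decision-making unit (DMU;
here, one drug).  Roles follow the production-economics convention:

* ``input`` — resources consumed; strictly positive (e.g. doses per day);
* ``desirable_output`` — benefits, any real value (e.g. HbA1c reduction in
  percentage points, weight change with loss positive and gain negative);
* ``undesirable_output`` — harms where less is better, any real value
  (e.g. all-cause mortality odds ratio vs placebo).

The frontier model consumes panels through the ``matrix`` accessors, which
return one column per variable of the requested role, in schema order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import SchemaError, UnknownUnitError, ValidationError


class Role(str, enum.Enum):
    INPUT = "input"
    DESIRABLE = "desirable_output"
    UNDESIRABLE = "undesirable_output"


@dataclass(frozen=True)
class Variable:
    """One column of the benchmark table: a name, a role, and a unit label."""

    name: str
    role: Role
    unit_label: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("variable name must be non-empty")
        object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class VariableSchema:
    """Declares the model's variables and their roles.

    Invariants: names are unique; there is at least one input and at least
    one output (desirable or undesirable).
    """

    variables: tuple[Variable, ...]

    def __init__(self, variables: Iterable[Variable | Mapping]) -> None:
        entries = tuple(
            v if isinstance(v, Variable) else Variable(**v) for v in variables
        )
        object.__setattr__(self, "variables", entries)
        names = [v.name for v in entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate variable names: {dupes}")
        if not self.names(Role.INPUT):
            raise SchemaError("schema needs at least one input variable")
        if not (self.names(Role.DESIRABLE) or self.names(Role.UNDESIRABLE)):
            raise SchemaError("schema needs at least one output variable")

    def names(self, role: Role | None = None) -> tuple[str, ...]:
        """Variable names, optionally restricted to one role, in schema order."""
        return tuple(
            v.name for v in self.variables if role is None or v.role is role
        )

    def role_of(self, name: str) -> Role:
        for v in self.variables:
            if v.name == name:
                return v.role
        raise SchemaError(f"unknown variable {name!r}")

    def __len__(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class UnitProfile:
    """One drug: identifier, optional metadata, and its variable values."""

    id: str
    values: Mapping[str, float]
    class_label: str | None = None
    approval_year: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("unit id must be non-empty")
        object.__setattr__(self, "values", dict(self.values))
        if self.approval_year is not None:
            object.__setattr__(self, "approval_year", int(self.approval_year))


@dataclass(frozen=True)
class Panel:
    """The full benchmark set: schema plus n ≥ 2 conforming units.

    Validation enforces the frontier model's domain: every unit covers
    exactly the schema's variables, all values are finite, and every input
    value is strictly positive (outputs may be negative).
    """

    schema: VariableSchema
    units: tuple[UnitProfile, ...]
    _matrices: dict = field(default_factory=dict, repr=False, compare=False)

    def __init__(self, schema: VariableSchema, units: Iterable[UnitProfile]) -> None:
        object.__setattr__(self, "schema", schema)
        object.__setattr__(self, "units", tuple(units))
        object.__setattr__(self, "_matrices", {})
        self._validate()

    def _validate(self) -> None:
        if len(self.units) < 2:
            raise ValidationError(
                f"a panel needs at least 2 units, got {len(self.units)}"
            )
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate unit ids: {dupes}")
        expected = set(self.schema.names())
        inputs = set(self.schema.names(Role.INPUT))
        for u in self.units:
            got = set(u.values)
            if got != expected:
                missing, extra = sorted(expected - got), sorted(got - expected)
                raise ValidationError(
                    f"unit {u.id!r} does not match the schema "
                    f"(missing {missing}, unexpected {extra})"
                )
            for name, value in u.values.items():
                if not np.isfinite(value):
                    raise ValidationError(
                        f"unit {u.id!r}: variable {name!r} is not finite ({value!r})"
                    )
                if name in inputs and value <= 0:
                    raise ValidationError(
                        f"unit {u.id!r}: input {name!r} must be strictly "
                        f"positive, got {value!r}"
                    )

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(u.id for u in self.units)

    def index_of(self, unit_id: str) -> int:
        for i, u in enumerate(self.units):
            if u.id == unit_id:
                return i
        raise UnknownUnitError(f"unit {unit_id!r} is not in the panel")

    def unit(self, unit_id: str) -> UnitProfile:
        return self.units[self.index_of(unit_id)]

    def matrix(self, role: Role) -> np.ndarray:
        """n × k value matrix for one role, columns in schema order.

        Shapes are (n, 0) when the schema has no variable of that role, so
        downstream linear algebra needs no special-casing.
        """
        if role not in self._matrices:
            names = self.schema.names(role)
            mat = np.array(
                [[float(u.values[name]) for name in names] for u in self.units],
                dtype=float,
            ).reshape(self.n, len(names))
            mat.setflags(write=False)
            self._matrices[role] = mat
        return self._matrices[role]

    def with_units(self, units: Iterable[UnitProfile]) -> "Panel":
        """A new panel over the same schema (used when planting units)."""
        return Panel(self.schema, units)
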