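"""Exception hierarchy.

Validation problems (bad schema, bad panel, bad CSV) and solver problems are
kept distinct so the CLI can map them to different exit codes.
"""


class MedeffError(Exception):
    """Base class for all package errors."""


class ValidationError(MedeffError):
    """Input data or configuration violates a documented contract."""


class SchemaError(ValidationError):
    """Variable schema is malformed (duplicate names, missing roles...)."""


class UnknownUnitError(ValidationError, KeyError):
    """A unit id was requested that the panel does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ContractError(MedeffError):
    """An operation was handed objects that do not belong together."""


class SolverFailure(MedeffError):
    """The LP backend failed to return an optimal solution."""

    def __init__(self, message: str, unit_id: str | None = None):
        super().__init__(message)
        self.unit_id = unit_id


class PlantingError(MedeffError):
    """A synthetic unit could not be planted without creating new extremes."""

    def __init__(self, message: str, variable: str | None = None, theta: float | None = None):
        super().__init__(message)
        self.variable = variable
        self.theta = theta
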