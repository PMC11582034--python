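"""Run configuration: variable roles, tolerances, thresholds.

Loaded from YAML (or built in code).  A config declares which CSV columns
are model variables and with what role, plus the solver and analysis
settings.  When no config is supplied the CLI falls back to
:data:`DEFAULT_CONFIG`, which matches the column layout emitted by the
synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .dea import SolverOptions
from .errors import ValidationError
from .panel import Role, Variable, VariableSchema


@dataclass(frozen=True)
class RunConfig:
    variables: tuple[Variable, ...]
    id_column: str = "id"
    class_column: str = "class"
    year_column: str = "approval_year"
    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9
    efficiency_tol: float = 1e-7
    era_threshold_year: int = 2010
    reference_threshold: float = 0.01
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        # schema construction validates names/roles
        _ = self.schema
        if not 0.0 < self.reference_threshold < 1.0:
            raise ValidationError("reference_threshold must lie in (0, 1)")
        for name in ("feasibility_tol", "optimality_tol", "efficiency_tol"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")

    @property
    def schema(self) -> VariableSchema:
        return VariableSchema(self.variables)

    @property
    def solver_options(self) -> SolverOptions:
        return SolverOptions(
            feasibility_tol=self.feasibility_tol,
            optimality_tol=self.optimality_tol,
            efficient_tol=self.efficiency_tol,
        )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        var_entries = raw.pop("variables", None)
        if not var_entries:
            raise ValidationError("config must declare a 'variables' list")
        variables = tuple(
            Variable(
                name=e["name"],
                role=Role(e["role"]),
                unit_label=e.get("unit_label", ""),
            )
            for e in var_entries
        )
        known = {f.name for f in cls.__dataclass_fields__.values()} - {"variables"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(variables=variables, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise ValidationError(f"config file {path} is not a YAML mapping")
        return cls.from_dict(raw)


#: Matches the synthetic generator's compound-level column layout.
DEFAULT_CONFIG = RunConfig(
    variables=(
        Variable("dose_frequency", Role.INPUT, "per day"),
        Variable("hba1c_reduction", Role.DESIRABLE, "%"),
        Variable("weight_change", Role.DESIRABLE, "% (loss positive)"),
        Variable("mortality_or", Role.UNDESIRABLE, "odds ratio vs placebo"),
    )
)

#: Branded-level layout (no mortality column).
DEFAULT_BRANDED_CONFIG = RunConfig(
    variables=(
        Variable("dose_frequency", Role.INPUT, "per day"),
        Variable("hba1c_reduction", Role.DESIRABLE, "%"),
        Variable("weight_change", Role.DESIRABLE, "% (loss positive)"),
    )
)


def default_config_for_columns(columns: Sequence[str]) -> RunConfig:
    """Pick the default config whose variable set matches ``columns``.

    Used by the CLI when no explicit config is given; unknown layouts raise.
    """
    for cfg in (DEFAULT_CONFIG, DEFAULT_BRANDED_CONFIG):
        wanted = set(cfg.schema.names())
        meta = {cfg.id_column, cfg.class_column, cfg.year_column}
        if wanted <= set(columns) and set(columns) <= wanted | meta:
            return cfg
    raise ValidationError(
        "cannot infer variable roles from columns "
        f"{sorted(columns)}; supply a config file"
    )
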