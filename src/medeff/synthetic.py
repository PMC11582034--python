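"""Synthetic drug-profile panels and planted-inefficiency instances.

Two families of generators:

* :func:`generate_panel` draws class-structured drug profiles that mimic the
  published class-level summary statistics of marketed type-2-diabetes drugs
  (dose frequency on a small per-day support including weekly = 1/7; HbA1c
  reduction in percentage points, strictly positive; weight change in %,
  negative for weight-gaining classes; all-cause mortality odds ratio,
  log-normal around a class-specific log-OR).  Distribution shapes are this
  module's own choice — only class-level summaries are published — picked
  for positivity of the respective quantities (truncated normal for HbA1c,
  log-normal for the odds ratio).

* :func:`generate_recovery_instance` builds instances with known ground
  truth: a strictly concave increasing frontier (whose vertices define every
  panel extreme) plus units planted at a prescribed inefficiency θ.  Each
  planted unit is the unique point that, displaced by θ along its own
  range direction, lands exactly on a chosen frontier-facet anchor; solving
  the RDM on such an instance must recover the planted θ exactly, which
  makes these instances an end-to-end oracle for the whole scoring path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import truncnorm

from .errors import PlantingError, ValidationError
from .panel import Panel, Role, UnitProfile, Variable, VariableSchema

WEEKLY = 1.0 / 7.0  # weekly dosing expressed per day

#: Canonical variable schema for synthetic drug panels (compound level).
DRUG_SCHEMA = VariableSchema(
    [
        Variable("dose_frequency", Role.INPUT, "per day"),
        Variable("hba1c_reduction", Role.DESIRABLE, "%"),
        Variable("weight_change", Role.DESIRABLE, "% (loss positive)"),
        Variable("mortality_or", Role.UNDESIRABLE, "odds ratio vs placebo"),
    ]
)

#: Branded-level schema: no mortality column (FDA labels carry no such data).
BRANDED_SCHEMA = VariableSchema(
    [
        Variable("dose_frequency", Role.INPUT, "per day"),
        Variable("hba1c_reduction", Role.DESIRABLE, "%"),
        Variable("weight_change", Role.DESIRABLE, "% (loss positive)"),
    ]
)


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters for one drug class.

    Means/SDs are in the variable's own units (HbA1c and weight in %); the
    mortality parameters are on the log-odds-ratio scale.  ``weight_mean``
    may be negative (weight-gaining classes).
    """

    class_name: str
    dose_frequency_support: tuple[float, ...]
    hba1c_mean: float
    hba1c_sd: float
    weight_mean: float
    weight_sd: float
    mortality_log_or_mean: float = 0.0
    mortality_log_or_sd: float = 0.0
    units_per_class: int = 1
    approval_year_range: tuple[int, int] = (1995, 2023)

    def __post_init__(self) -> None:
        if self.units_per_class < 1:
            raise ValidationError("units_per_class must be positive")
        if min(self.hba1c_sd, self.weight_sd, self.mortality_log_or_sd) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if any(d <= 0 for d in self.dose_frequency_support):
            raise ValidationError("dose frequencies must be strictly positive")
        if self.hba1c_sd == 0 and self.hba1c_mean <= 0:
            raise ValidationError("degenerate HbA1c distribution must be positive")


#: Class-level parameters transcribed from published summary statistics of
#: FDA-approved type-2-diabetes drugs (dose-frequency supports from the
#: min/max per class; HbA1c and weight-change means/SDs as published; a
#: missing SD means the class has a single profile).  Mortality log-OR
#: parameters and approval-year windows are this module's own calibration:
#: newer incretin/SGLT2 classes mildly protective, older classes null.
DEFAULT_CLASS_PARAMS: tuple[ClassParams, ...] = (
    ClassParams("Sulfonylureas", (1.0,), 1.700, 0.0, 0.000, 0.0,
                0.05, 0.05, 1, (1984, 1994)),
    ClassParams("Biguanides", (1.0, 2.0), 1.068, 0.452, 0.000, 0.304,
                0.00, 0.05, 5, (1994, 2005)),
    ClassParams("Glinides", (2.0, 3.0), 0.450, 0.005, -2.815, 0.470,
                0.00, 0.05, 2, (1997, 2000)),
    ClassParams("Thiazolidinediones", (1.0,), 0.800, 0.0, -2.200, 0.0,
                0.00, 0.05, 1, (1999, 1999)),
    ClassParams("GLP-1 analogs", (WEEKLY, 1.0, 2.0), 0.884, 0.098, 2.344, 5.378,
                -0.128, 0.05, 7, (2005, 2022)),
    ClassParams("SGLT2 inhibitors", (1.0,), 0.642, 0.044, 2.338, 0.463,
                -0.163, 0.05, 5, (2013, 2023)),
    ClassParams("DPP-4 inhibitors", (1.0,), 0.667, 0.013, 0.000, 0.000,
                0.00, 0.05, 3, (2006, 2013)),
    ClassParams("Dopamine D2 receptors", (1.0,), 0.400, 0.0, -0.340, 0.0,
                0.00, 0.05, 1, (2009, 2009)),
    ClassParams("Combination oral pills", (1.0, 2.0), 0.884, 0.170, 0.489, 1.943,
                0.00, 0.05, 13, (2000, 2020)),
)


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name.lower()).strip("_")


def generate_panel(
    class_params_list: Sequence[ClassParams] = DEFAULT_CLASS_PARAMS,
    seed: int | np.random.Generator = 0,
    include_mortality: bool = True,
) -> Panel:
    """Draw a class-structured synthetic drug panel.

    Per unit: dose frequency uniform on the class support; HbA1c reduction
    from a normal truncated to (0, ∞); weight change from an untruncated
    normal (negative values arise whenever the class mean is negative or
    the SD allows); mortality OR as exp(normal).  Deterministic given the
    seed.
    """
    params = tuple(class_params_list)
    if not params:
        raise ValidationError("need at least one drug class")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    schema = DRUG_SCHEMA if include_mortality else BRANDED_SCHEMA
    units = []
    for cp in params:
        for k in range(cp.units_per_class):
            values = {
                "dose_frequency": float(rng.choice(cp.dose_frequency_support)),
                "hba1c_reduction": _positive_normal(rng, cp.hba1c_mean, cp.hba1c_sd),
                "weight_change": float(rng.normal(cp.weight_mean, cp.weight_sd))
                if cp.weight_sd > 0 else cp.weight_mean,
            }
            if include_mortality:
                log_or = (
                    float(rng.normal(cp.mortality_log_or_mean, cp.mortality_log_or_sd))
                    if cp.mortality_log_or_sd > 0 else cp.mortality_log_or_mean
                )
                values["mortality_or"] = float(np.exp(log_or))
            y0, y1 = cp.approval_year_range
            units.append(
                UnitProfile(
                    id=f"{_slug(cp.class_name)}_{k + 1}",
                    values=values,
                    class_label=cp.class_name,
                    approval_year=int(rng.integers(y0, y1 + 1)),
                )
            )
    return Panel(schema, units)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(mean)
    a = (0.0 - mean) / sd  # truncate at zero: HbA1c reductions are positive
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def random_panel(
    seed: int | np.random.Generator,
    n_units: int,
    n_inputs: int = 1,
    n_desirable: int = 1,
    n_undesirable: int = 0,
    with_years: bool = True,
) -> Panel:
    """Unstructured random panel for property testing.

    Inputs uniform on (0.5, 3); desirable outputs normal(0, 2) so negative
    values occur routinely; undesirable outputs normal(1, 0.5) (may dip
    negative, which the model permits).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    variables = (
        [Variable(f"in_{j + 1}", Role.INPUT) for j in range(n_inputs)]
        + [Variable(f"des_{r + 1}", Role.DESIRABLE) for r in range(n_desirable)]
        + [Variable(f"und_{f + 1}", Role.UNDESIRABLE) for f in range(n_undesirable)]
    )
    schema = VariableSchema(variables)
    units = []
    for i in range(n_units):
        values = {}
        for v in variables:
            if v.role is Role.INPUT:
                values[v.name] = float(rng.uniform(0.5, 3.0))
            elif v.role is Role.DESIRABLE:
                values[v.name] = float(rng.normal(0.0, 2.0))
            else:
                values[v.name] = float(rng.normal(1.0, 0.5))
        units.append(
            UnitProfile(
                id=f"u{i + 1:03d}",
                values=values,
                approval_year=int(rng.integers(1995, 2024)) if with_years else None,
            )
        )
    return Panel(schema, units)


# ---------------------------------------------------------------------------
# planted-inefficiency instances


@dataclass(frozen=True)
class PlantedInstance:
    """A panel with ground-truth inefficiencies for the planted units."""

    panel: Panel
    planted: Mapping[str, float]
    facet_anchor: Mapping[str, Mapping[str, float]]


def plant_inefficient_unit(
    panel: Panel,
    anchor_point: Mapping[str, float],
    theta: float,
    unit_id: str = "planted",
    enforce_box: bool = False,
) -> UnitProfile:
    """Construct the unit whose RDM displacement by ``theta`` hits ``anchor_point``.

    Solves the per-variable fixed point: displacement along the unit's own
    range direction must land on the anchor, i.e. (1−θ)v + θ·extreme = p,
    where the extreme is the panel minimum for inputs/undesirable outputs
    and the panel maximum for desirable outputs.  Hence

        v = (p − θ·extreme) / (1 − θ).

    Validation always rejects plantings that would create a new
    *frontier-relevant* extreme (a new input or undesirable-output minimum,
    or a new desirable-output maximum), since those would change every
    unit's ranges.  With ``enforce_box=True`` the planted value must also
    stay inside the opposite, model-irrelevant extremes (used by the
    recovery generator so that anchors define all extremes of the
    instance).  Violations raise :class:`PlantingError` naming the
    offending variable.  Exact recovery (θ* = θ) additionally needs the
    anchor in the strict interior of an efficient facet; a vertex anchor
    only guarantees θ* ≥ θ.
    """
    if not 0.0 <= theta < 1.0:
        raise ValidationError(f"theta must lie in [0, 1), got {theta!r}")
    if set(anchor_point) != set(panel.schema.names()):
        raise ValidationError("anchor point must cover exactly the schema's variables")
    values: dict[str, float] = {}
    for var in panel.schema.variables:
        col = panel.matrix(var.role)[
            :, panel.schema.names(var.role).index(var.name)
        ]
        lo, hi = float(col.min()), float(col.max())
        p = float(anchor_point[var.name])
        if var.role is Role.DESIRABLE:
            v = (p - theta * hi) / (1.0 - theta)
            if v > hi + 1e-12:
                raise PlantingError(
                    f"planting at theta={theta} would create a new maximum "
                    f"{v:.6g} for desirable output {var.name!r} (panel max {hi:.6g})",
                    variable=var.name, theta=theta,
                )
            v = min(v, hi)
            boxed = v >= lo - 1e-12
        else:
            v = (p - theta * lo) / (1.0 - theta)
            if v < lo - 1e-12:
                raise PlantingError(
                    f"planting at theta={theta} would create a new minimum "
                    f"{v:.6g} for {var.name!r} (panel min {lo:.6g})",
                    variable=var.name, theta=theta,
                )
            v = max(v, lo)
            boxed = v <= hi + 1e-12
        if enforce_box and not boxed:
            raise PlantingError(
                f"planting at theta={theta} would push {var.name!r} to {v:.6g}, "
                f"outside the panel range [{lo:.6g}, {hi:.6g}]",
                variable=var.name, theta=theta,
            )
        values[var.name] = float(v)
    return UnitProfile(id=unit_id, values=values, class_label="planted")


def generate_recovery_instance(
    n_frontier: int,
    planted_thetas: Sequence[float],
    seed: int | np.random.Generator = 0,
    max_retries: int = 100,
) -> PlantedInstance:
    """Frontier of mutually non-dominated anchors plus planted units.

    The frontier vertices lie on a strictly concave, strictly increasing
    saturating curve y = y0 + s·(1 − exp(−k(x − x0))) over one input and one
    desirable output, so every vertex is efficient under variable returns
    to scale and adjacent vertices span efficient facets.  Each planted θ
    gets a random facet-interior anchor; anchors are redrawn (up to
    ``max_retries``) when the fixed-point displacement would leave the
    anchor-defined extremes, and an error reports the failing θ otherwise.
    """
    if n_frontier < 2:
        raise ValidationError("need at least 2 frontier units")
    if any(not 0.0 <= t < 1.0 for t in planted_thetas):
        raise ValidationError("planted thetas must lie in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    schema = VariableSchema(
        [Variable("input_1", Role.INPUT), Variable("output_1", Role.DESIRABLE)]
    )
    x0, x1 = 1.0, float(rng.uniform(3.0, 5.0))
    y0 = float(rng.uniform(1.0, 3.0))
    s = float(rng.uniform(5.0, 15.0))
    k = float(rng.uniform(1.5, 3.0))
    xs = np.linspace(x0, x1, n_frontier)
    ys = y0 + s * (1.0 - np.exp(-k * (xs - x0)))
    anchors = [
        UnitProfile(
            id=f"frontier_{i + 1}",
            values={"input_1": float(x), "output_1": float(y)},
            class_label="frontier",
        )
        for i, (x, y) in enumerate(zip(xs, ys))
    ]
    anchor_panel = Panel(schema, anchors)

    planted_units: list[UnitProfile] = []
    planted: dict[str, float] = {}
    facet_anchor: dict[str, dict[str, float]] = {}
    for j, theta in enumerate(planted_thetas):
        unit = None
        for _ in range(max_retries):
            facet = int(rng.integers(0, n_frontier - 1))
            t = float(rng.uniform(0.15, 0.85))
            p = {
                "input_1": float((1 - t) * xs[facet] + t * xs[facet + 1]),
                "output_1": float((1 - t) * ys[facet] + t * ys[facet + 1]),
            }
            try:
                unit = plant_inefficient_unit(
                    anchor_panel, p, theta,
                    unit_id=f"planted_{j + 1}", enforce_box=True,
                )
            except PlantingError:
                continue
            break
        if unit is None:
            raise PlantingError(
                f"could not plant a unit at theta={theta} within "
                f"{max_retries} anchor draws",
                theta=theta,
            )
        planted_units.append(unit)
        planted[unit.id] = float(theta)
        facet_anchor[unit.id] = {"facet": float(facet), "t": t, **p}

    return PlantedInstance(
        panel=Panel(schema, [*anchors, *planted_units]),
        planted=planted,
        facet_anchor=facet_anchor,
    )
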