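"""Range directional DEA model (RDM) under variable returns to scale.

The RDM scores each decision-making unit o against the frontier spanned by
convex combinations of all n units.  Its improvement direction is the unit's
own *range of possible improvement*:

    R_x[j] = x_oj − min_i x_ij          (inputs)
    R_y[r] = max_i y_ir − y_or          (desirable outputs)
    R_z[f] = z_of − min_i z_if          (undesirable outputs, input-like)

and the inefficiency score θ* is the optimum of the linear program

    max θ   s.t.  Σ λ_i x_ij + θ R_x[j] ≤ x_oj        j = 1..m
                  Σ λ_i y_ir − θ R_y[r] ≥ y_or        r = 1..s
                  Σ λ_i z_if + θ R_z[f] ≤ z_of        f = 1..h
                  Σ λ_i = 1,  λ ≥ 0,  0 ≤ θ ≤ 1

Efficiency is 1 − θ*.  Because the direction is the unit's own range, the
score is invariant to translating any output column and to rescaling any
variable column, which is what makes the model well defined for negative
data (weight gain) and for harms treated as undesirable outputs.

Slacks are computed by the standard second phase: θ is fixed at θ* and the
sum of range-normalised residual slacks is maximised subject to the same
envelopment constraints.  Normalising by each variable's range makes slacks
comparable across variables measured in different units (doses/day vs % HbA1c).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import ContractError, SolverFailure, ValidationError
from .panel import Panel, Role

logger = logging.getLogger(__name__)

#: Below this, a range (always ≥ 0 by construction) is treated as exactly zero.
_ZERO_RANGE_TOL = 1e-12


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    NUMERICAL_FAILURE = "numerical_failure"


@dataclass(frozen=True)
class SolverOptions:
    """LP backend settings.

    feasibility_tol / optimality_tol are handed to HiGHS; reference_threshold
    is the reporting cutoff for including a peer in the reference set;
    efficient_tol declares a unit efficient when θ* falls below it.
    """

    feasibility_tol: float = 1e-9
    optimality_tol: float = 1e-9
    reference_threshold: float = 1e-6
    efficient_tol: float = 1e-7

    def _linprog_options(self) -> dict:
        return {
            "presolve": True,
            "primal_feasibility_tolerance": self.feasibility_tol,
            "dual_feasibility_tolerance": self.optimality_tol,
        }


@dataclass(frozen=True)
class RangeSet:
    """Per-variable ranges of possible improvement for one evaluated unit."""

    unit_id: str
    input_ranges: Mapping[str, float]
    desirable_ranges: Mapping[str, float]
    undesirable_ranges: Mapping[str, float]

    def of(self, name: str) -> float:
        for m in (self.input_ranges, self.desirable_ranges, self.undesirable_ranges):
            if name in m:
                return m[name]
        raise KeyError(name)

    def all_zero(self) -> bool:
        vals = [
            *self.input_ranges.values(),
            *self.desirable_ranges.values(),
            *self.undesirable_ranges.values(),
        ]
        return all(v <= _ZERO_RANGE_TOL for v in vals)


@dataclass(frozen=True)
class EfficiencyResult:
    """Optimal RDM solution for one unit.

    ``lambdas`` holds the intensity weights at the optimal vertex returned by
    the solver.  The weights are generally non-unique (alternate optimal
    bases), so ``reference_set`` is *an* optimal reference set.
    """

    unit_id: str
    theta_star: float
    efficiency: float
    lambdas: Mapping[str, float]
    reference_set: tuple[str, ...]
    solver_status: SolverStatus

    @property
    def is_optimal(self) -> bool:
        return self.solver_status is SolverStatus.OPTIMAL


@dataclass(frozen=True)
class SlackReport:
    """Phase-II residual slacks for one unit.

    ``raw_slack`` is in each variable's own units; ``normalized_slack``
    divides by that variable's range (defined as 0 when the range is 0) so
    slacks are dimensionless and comparable across variables.
    ``largest_slack_variable`` is None when every slack is numerically zero
    (the unit projects exactly onto the frontier benchmark).  ``lambdas``
    holds the phase-II intensity weights, so the projected point
    (inputs − θ*R − slack, outputs + θ*R + slack) equals the λ-combination
    of the panel component-wise.
    """

    unit_id: str
    raw_slack: Mapping[str, float]
    normalized_slack: Mapping[str, float]
    largest_slack_variable: str | None
    lambdas: Mapping[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ranges


def compute_ranges(panel: Panel, o: str) -> RangeSet:
    """Ranges of possible improvement for unit ``o`` against the panel.

    Inputs and undesirable outputs use distance to the panel minimum,
    desirable outputs distance to the panel maximum; all ranges are ≥ 0 and
    a zero range means the unit already attains that panel extreme.
    """
    i = panel.index_of(o)
    out: dict[Role, dict[str, float]] = {}
    for role in (Role.INPUT, Role.DESIRABLE, Role.UNDESIRABLE):
        mat = panel.matrix(role)
        names = panel.schema.names(role)
        if mat.shape[1] == 0:
            out[role] = {}
        elif role is Role.DESIRABLE:
            r = mat.max(axis=0) - mat[i]
            out[role] = dict(zip(names, r.tolist()))
        else:
            r = mat[i] - mat.min(axis=0)
            out[role] = dict(zip(names, r.tolist()))
    return RangeSet(
        unit_id=o,
        input_ranges=out[Role.INPUT],
        desirable_ranges=out[Role.DESIRABLE],
        undesirable_ranges=out[Role.UNDESIRABLE],
    )


def _constraint_arrays(panel: Panel, o: str):
    """Stack all envelopment constraints in '≤' form.

    Returns (A, b, R, names, roles) with one row per variable, such that a
    weight vector λ satisfies constraint c at inefficiency θ iff
    ``A[c] @ λ + θ R[c] ≤ b[c]``.  Desirable-output rows are negated to fit
    the '≤' convention.
    """
    i = panel.index_of(o)
    rs = compute_ranges(panel, o)
    blocks, bs, Rs, names, roles = [], [], [], [], []
    for role, ranges, sign in (
        (Role.INPUT, rs.input_ranges, 1.0),
        (Role.DESIRABLE, rs.desirable_ranges, -1.0),
        (Role.UNDESIRABLE, rs.undesirable_ranges, 1.0),
    ):
        mat = panel.matrix(role)
        if mat.shape[1] == 0:
            continue
        blocks.append(sign * mat.T)          # one row per variable
        bs.append(sign * mat[i])
        Rs.extend(ranges[n] for n in panel.schema.names(role))
        names.extend(panel.schema.names(role))
        roles.extend([role] * mat.shape[1])
    A = np.vstack(blocks)
    b = np.concatenate(bs)
    R = np.asarray(Rs, dtype=float)
    return A, b, R, names, roles, rs


# ---------------------------------------------------------------------------
# phase I: the RDM score


def solve_rdm(
    panel: Panel, o: str, options: SolverOptions | None = None
) -> EfficiencyResult:
    """Solve the RDM linear program for unit ``o``.

    Returns θ* clamped to [0, 1], efficiency 1 − θ*, and the intensity
    weights at the solver's optimal vertex.  A unit whose every range is
    zero is the panel's ideal point: by convention it gets θ* = 0 with
    itself as sole reference (the LP objective would otherwise be vacuous
    in θ).  An infeasible status is impossible for a valid panel
    (λ_o = 1, θ = 0 is always feasible) and therefore raises; other solver
    breakdowns are reported as ``numerical_failure`` with NaN scores rather
    than a fabricated value.
    """
    opts = options or SolverOptions()
    idx = panel.index_of(o)
    A, b, R, _, _, rs = _constraint_arrays(panel, o)
    n = panel.n

    if rs.all_zero():
        lambdas = {uid: (1.0 if uid == o else 0.0) for uid in panel.ids}
        return EfficiencyResult(
            unit_id=o,
            theta_star=0.0,
            efficiency=1.0,
            lambdas=lambdas,
            reference_set=(o,),
            solver_status=SolverStatus.OPTIMAL,
        )

    n_con = A.shape[0]
    logger.debug(
        "RDM LP for %s: %d decision variables (theta + %d lambdas), %d rows",
        o, n + 1, n, n_con,
    )
    # variables: [theta, lambda_1..lambda_n]
    c = np.zeros(n + 1)
    c[0] = -1.0  # maximise theta
    A_ub = np.hstack([R.reshape(-1, 1), A])
    A_eq = np.zeros((1, n + 1))
    A_eq[0, 1:] = 1.0
    bounds = [(0.0, 1.0)] + [(0.0, None)] * n

    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b,
        A_eq=A_eq,
        b_eq=[1.0],
        bounds=bounds,
        method="highs",
        options=opts._linprog_options(),
    )

    if res.status == 2:
        raise SolverFailure(
            f"RDM LP reported infeasible for unit {o!r}; this cannot happen "
            "for a valid panel and indicates an implementation bug",
            unit_id=o,
        )
    if res.status != 0:
        logger.warning("solver failure for %s: %s", o, res.message)
        return EfficiencyResult(
            unit_id=o,
            theta_star=float("nan"),
            efficiency=float("nan"),
            lambdas={},
            reference_set=(),
            solver_status=SolverStatus.NUMERICAL_FAILURE,
        )

    theta = float(np.clip(res.x[0], 0.0, 1.0)) or 0.0  # normalise -0.0
    lam = np.clip(res.x[1:], 0.0, None)
    lambdas = dict(zip(panel.ids, lam.tolist()))
    reference = tuple(
        uid for uid, w in lambdas.items() if w > opts.reference_threshold
    )
    logger.info("unit %s: theta*=%.6f efficiency=%.6f", o, theta, 1.0 - theta)
    return EfficiencyResult(
        unit_id=o,
        theta_star=theta,
        efficiency=1.0 - theta,
        lambdas=lambdas,
        reference_set=reference,
        solver_status=SolverStatus.OPTIMAL,
    )


def evaluate_all(
    panel: Panel, options: SolverOptions | None = None
) -> tuple[EfficiencyResult, ...]:
    """Solve the RDM once per unit, in panel order.

    Deterministic for identical panel and options.  A per-unit numerical
    failure is escalated with the failing unit identified.
    """
    results = []
    for uid in panel.ids:
        res = solve_rdm(panel, uid, options)
        if not res.is_optimal:
            raise SolverFailure(
                f"solver failed while scoring unit {uid!r}", unit_id=uid
            )
        results.append(res)
    return tuple(results)


# ---------------------------------------------------------------------------
# phase II: slacks


def compute_slacks(
    panel: Panel,
    o: str,
    result: EfficiencyResult,
    options: SolverOptions | None = None,
) -> SlackReport:
    """Maximal residual slacks at the phase-I optimum.

    With θ fixed at θ*, maximises Σ s_v / R_v over variables with positive
    range, subject to the envelopment constraints written as equalities with
    explicit slack variables:

        Σ λ x_ij + s_x[j] = x_oj − θ* R_x[j]
        Σ λ y_ir − s_y[r] = y_or + θ* R_y[r]
        Σ λ z_if + s_z[f] = z_of − θ* R_z[f]
        Σ λ = 1,  λ, s ≥ 0

    Variables with zero range carry a zero objective weight and a
    normalised slack defined as 0.  Ties in the largest normalised slack
    (within 1e−9) go to the variable earliest in schema order.
    """
    opts = options or SolverOptions()
    if result.unit_id != o:
        raise ContractError(
            f"result is for unit {result.unit_id!r}, not {o!r}"
        )
    if not result.is_optimal:
        raise ContractError("slacks require an optimal phase-I result")

    A, b, R, names, _, rs = _constraint_arrays(panel, o)
    n, n_con = panel.n, A.shape[0]

    if rs.all_zero():
        zeros = {v: 0.0 for v in names}
        lam = {uid: (1.0 if uid == o else 0.0) for uid in panel.ids}
        return SlackReport(o, dict(zeros), dict(zeros), None, lam)

    theta = result.theta_star
    res = _solve_phase2(A, b, R, n, n_con, theta, opts)
    if res is None:
        # theta* sits on the feasibility boundary; retreat by one feasibility
        # tolerance and retry before giving up.
        res = _solve_phase2(
            A, b, R, n, n_con, max(theta - 10 * opts.feasibility_tol, 0.0), opts
        )
    if res is None:
        raise SolverFailure(
            f"phase-II slack LP failed for unit {o!r}", unit_id=o
        )

    raw = np.clip(res.x[n:], 0.0, None)
    pos = R > _ZERO_RANGE_TOL
    norm = np.where(pos, raw / np.where(pos, R, 1.0), 0.0)
    raw_map = dict(zip(names, raw.tolist()))
    norm_map = dict(zip(names, norm.tolist()))

    largest = None
    max_norm = float(norm.max()) if len(norm) else 0.0
    if max_norm > 1e-9:
        near = np.flatnonzero(max_norm - norm <= 1e-9)
        if len(near) > 1:
            logger.info(
                "unit %s: largest-slack tie between %s; attributing to the "
                "first in schema order", o, [names[i] for i in near],
            )
        largest = names[int(near[0])]
    lam = dict(zip(panel.ids, np.clip(res.x[:n], 0.0, None).tolist()))
    return SlackReport(o, raw_map, norm_map, largest, lam)


def _solve_phase2(A, b, R, n, n_con, theta, opts):
    # variables: [lambda_1..lambda_n, s_1..s_{n_con}]; every constraint row
    # already uses the '≤' convention, so each slack enters with +1.
    c = np.zeros(n + n_con)
    pos = R > _ZERO_RANGE_TOL
    c[n:][pos] = -1.0 / R[pos]  # maximise normalised slack sum
    A_eq = np.zeros((n_con + 1, n + n_con))
    A_eq[:n_con, :n] = A
    A_eq[:n_con, n:] = np.eye(n_con)
    A_eq[n_con, :n] = 1.0
    b_eq = np.concatenate([b - theta * R, [1.0]])
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0.0, None)] * (n + n_con),
        method="highs",
        options=opts._linprog_options(),
    )
    return res if res.status == 0 else None


# ---------------------------------------------------------------------------
# reference sets


def reference_weights(
    result: EfficiencyResult, threshold: float = 0.01
) -> dict[str, float]:
    """Reference decomposition: λ entries above ``threshold``, renormalised.

    The returned weights sum to 1 and are ordered by descending weight
    (ties by unit id).  Because the optimal basis is generally non-unique,
    this is one valid decomposition, not the only one.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(
            f"reference threshold must lie in (0, 1), got {threshold!r}"
        )
    if not result.is_optimal:
        raise ContractError("reference weights require an optimal result")
    kept = {u: w for u, w in result.lambdas.items() if w > threshold}
    total = sum(kept.values())
    if not kept or total <= 0:
        raise ContractError(
            "no weight above threshold; weights summing to 1 guarantee at "
            "least one entry >= 1/n, so the threshold is too high"
        )
    ordered = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return {u: w / total for u, w in ordered}
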