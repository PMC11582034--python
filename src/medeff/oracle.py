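"""Brute-force grid oracle for the RDM score.

Independent cross-check for the linear-programming solver: enumerate the
intensity weights λ over a regular grid on the (n−1)-simplex and, for each
grid point, compute the largest feasible inefficiency θ directly from the
constraint ratios.  No linear programming is involved, so agreement between
this search and the LP optimum is evidence for the LP assembly, not a
restatement of it.

For each λ the largest feasible θ is

    min over constraints with positive range of  residual(λ) / range

where residual is ``x_oj − Σλx_ij`` for inputs, ``Σλy_ir − y_or`` for
desirable outputs and ``z_of − Σλz_if`` for undesirable outputs.  A
zero-range constraint contributes +∞ when its residual is satisfiable and
−∞ (λ infeasible) otherwise.  The maximum over the grid, clamped to [0, 1],
is a lower bound on θ* that converges to it as the grid refines; the grid
step therefore bounds the expected discrepancy.

The grid is enumerated exactly (no sampling): the last three simplex
coordinates are vectorised as a 2-D triangle and any remaining coordinates
are looped.  Point counts grow as C(g+n−1, n−1), so fine grids are practical
up to n = 4 and coarse grids up to n = 6.
"""

from __future__ import annotations

import numpy as np

from .dea import _ZERO_RANGE_TOL, _constraint_arrays
from .errors import ValidationError
from .panel import Panel

_FEAS_TOL = 1e-9


def brute_force_theta(panel: Panel, o: str, grid_points: int = 500) -> float:
    """Approximate θ* for unit ``o`` by exhaustive simplex-grid search.

    ``grid_points`` is the number of subdivisions per simplex axis; the
    returned value underestimates the LP optimum by at most a few grid
    steps on well-scaled data (the search only ever visits feasible
    points).  n ≤ 6 is recommended; the caller controls resolution and a
    too-coarse grid is not detectable internally.
    """
    if grid_points < 1:
        raise ValidationError("grid_points must be >= 1")
    A, b, R, _, _, rs = _constraint_arrays(panel, o)
    if rs.all_zero():
        # Ideal-point convention, mirroring the scoring model: a unit at
        # every panel extreme is efficient by definition.
        return 0.0

    g = grid_points
    n = panel.n
    finite = R > _ZERO_RANGE_TOL
    # residual(λ) = b_c − A[c]·λ for every row (desirable rows pre-negated)
    if n == 2:
        t = np.arange(g + 1)
        lam = np.stack([t, g - t], axis=1) / g           # (g+1, 2)
        resid = b[None, :] - lam @ A.T                   # (g+1, C)
        theta = _theta_from_residuals(resid, R, finite)
        best = float(theta.max())
    else:
        best = -np.inf
        # 2-D triangle over the last three coordinates (u, v, M−u−v);
        # affine fields in (u, v) are precomputed once at full size and
        # sliced per prefix, which keeps the inner loop to adds and mins.
        u = np.arange(g + 1, dtype=float)
        U, V = u[:, None], u[None, :]
        S = U + V                                        # for the validity mask
        ap, aq, ar = A[:, -3], A[:, -2], A[:, -1]
        # residual = b_c − prefix_c − [ (ap−ar) u + (aq−ar) v + ar M ] / g
        fields = [
            -((ap[c] - ar[c]) * U + (aq[c] - ar[c]) * V) / g
            for c in range(A.shape[0])
        ]
        n_prefix = n - 3
        for prefix in _compositions_at_most(g, n_prefix):
            used = sum(prefix)
            M = g - used
            sl = slice(0, M + 1)
            valid = S[sl, sl] <= M
            theta = None
            feasible = valid
            for c in range(A.shape[0]):
                pre = float(np.dot(A[c, :n_prefix], prefix)) / g if n_prefix else 0.0
                const = b[c] - pre - ar[c] * M / g
                resid = const + fields[c][sl, sl]
                if finite[c]:
                    val = resid / R[c]
                    theta = val if theta is None else np.minimum(theta, val)
                else:
                    feasible = feasible & (resid >= -_FEAS_TOL)
            if theta is None:  # all constraints zero-range but not all ranges zero: impossible
                continue
            theta = np.where(feasible, theta, -np.inf)
            m = float(theta.max())
            if m > best:
                best = m
    return float(np.clip(best, 0.0, 1.0))


def _theta_from_residuals(resid: np.ndarray, R: np.ndarray, finite: np.ndarray) -> np.ndarray:
    theta = np.full(resid.shape[0], np.inf)
    for c in range(resid.shape[1]):
        if finite[c]:
            theta = np.minimum(theta, resid[:, c] / R[c])
        else:
            theta = np.where(resid[:, c] >= -_FEAS_TOL, theta, -np.inf)
    return theta


def _compositions_at_most(total: int, k: int):
    """All k-tuples of non-negative ints with sum ≤ total (k may be 0)."""
    if k == 0:
        yield ()
        return
    for head in range(total + 1):
        for tail in _compositions_at_most(total - head, k - 1):
            yield (head, *tail)
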