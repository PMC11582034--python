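# Methods

## Model

The package scores decision-making units (drugs) with the range directional
model (RDM), a directional-distance DEA formulation whose improvement
direction is each unit's own *range of possible improvement*: distance to the
panel minimum for inputs and undesirable outputs, distance to the panel
maximum for desirable outputs.  The frontier is the variable-returns-to-scale
(VRS) envelope — convex combinations of observed units with intensity weights
λ summing to 1.  The score θ\* ∈ [0, 1] is the largest common fraction of all
ranges the unit could move simultaneously (contracting inputs, expanding
desirable outputs, reducing undesirable outputs) while staying enveloped;
efficiency is 1 − θ\*.

Assumptions worth making explicit:

- **Convexity / linear substitutability.** Benchmarks are convex combinations
  of observed drugs.  Pharmacologically this presumes linear dose–response
  and additivity when a reference mix is read as a hypothetical combination
  therapy; the package reports reference weights but makes no feasibility
  claim for such combinations.
- **Undesirable outputs are treated like inputs** through their own range
  (lower is better), which keeps the LP linear and the score monotone in
  harms.
- **Inputs strictly positive; outputs any sign.** Validation enforces this at
  panel construction and CSV ingestion.  Sign conventions are fixed at
  ingestion and never flipped silently: HbA1c reduction positive-is-good,
  weight change with loss positive, mortality as an odds ratio.

Translation invariance (shifting an output column) and unit invariance
(rescaling any column) hold analytically — both sides of each constraint
shift/scale identically — and are verified numerically to 1e−8 in the test
suite.

## Numerical choices

- **LP backend**: `scipy.optimize.linprog` with HiGHS, primal/dual
  feasibility tolerances 1e−9, presolve on.  HiGHS is deterministic at fixed
  inputs, which makes the whole pipeline byte-reproducible.
- **θ bounds**: θ is explicitly bounded to [0, 1].  The degenerate unit whose
  every range is zero (it attains every panel extreme simultaneously) makes
  θ's coefficient vanish in all constraints; the LP objective would then be
  vacuous and the solver would return the upper bound.  Such a unit is the
  panel's ideal point and must be efficient, so both the solver wrapper and
  the grid oracle short-circuit this case to θ\* = 0 with λ_o = 1.
- **Zero-range constraints** are kept in the LP unchanged (the θ term simply
  vanishes); no row dropping.
- **Feasibility**: the RDM LP is always feasible (λ_o = 1, θ = 0), so an
  "infeasible" status is escalated as an implementation bug rather than
  reported as a score.  Other solver breakdowns yield a `numerical_failure`
  status with NaN scores — never a fabricated value — and `evaluate_all`
  raises naming the failing unit.
- **Efficiency-1 tolerance**: a unit is called efficient when θ\* < 1e−7.
  Stored results keep full precision; rounding (3 decimals) happens only in
  the presentation-layer ranking CSV.
- **Alternate optima**: λ at the optimum is generally non-unique.  The
  package returns the solver's optimal vertex and documents that reference
  sets are *an* optimal decomposition.

## Slacks (phase II)

Raw slacks in mixed units (doses/day vs % HbA1c) are not comparable, so the
second phase fixes θ = θ\* and maximises the **sum of range-normalised
slacks** Σ s_v / R_v over variables with positive range, subject to the same
envelopment constraints written as equalities with explicit slack variables.
Variables with zero range get normalised slack defined as 0 (they are already
at their extreme) and zero objective weight.  Both raw and normalised slacks
are reported.  The largest normalised slack identifies the variable keeping
the drug off the frontier; ties within 1e−9 are attributed to the variable
earliest in schema order and logged.  If θ\* sits exactly on the feasibility
boundary, the phase-II LP is retried once with θ reduced by ten feasibility
tolerances before failing.

A geometric note: with a single input and a single desirable output, the
range direction points strictly into the frontier interior whenever both
ranges are positive, so the phase-I projection lands on the strong frontier
and slacks are zero even for dominated units.  Positive slacks arise with ≥ 3
variables, when one envelopment constraint is non-binding at the optimum; the
test suite demonstrates both behaviours on constructed fixtures.

## Grid oracle

`brute_force_theta` enumerates λ on a regular grid over the (n−1)-simplex and
computes, for each λ, the largest feasible θ directly from constraint ratios
(+∞ for satisfiable zero-range constraints, −∞ for violated ones), returning
the grid maximum clamped to [0, 1].  It is a feasible-point search, so it
never exceeds the LP optimum, and it approaches it from below as the grid
refines.  Enumeration is exact — the last three simplex coordinates are
vectorised as a 2-D triangle, remaining coordinates looped — and the point
count grows as C(g+n−1, n−1), making fine grids (500 subdivisions) practical
for n ≤ 4 and coarse grids (40–60) for n = 5, 6.  Tests exercise both
regimes; the oracle-agreement check runs 200 random instances with n ∈
{2, 3, 4} at 500 subdivisions, accepting the LP when it is within 2 grid
steps of the search on ≥ 99% of instances (the discrepancy bound scales with
the data's Lipschitz constant relative to the ranges, hence the 1% allowance
for ill-conditioned draws).

## Synthetic data

`generate_panel` emulates the class-level structure of marketed
type-2-diabetes drugs: nine classes (sulfonylureas through combination
pills), each with a finite dose-frequency support (weekly = 1/7/day; the
glinides dose 2–3×/day), HbA1c reduction from a normal truncated to > 0,
weight change from an untruncated normal — classes with negative means
(glinides −2.815 ± 0.47 %, thiazolidinediones, dopamine-D2 agonists) produce
weight gain — and mortality OR as exp(normal).  Class counts follow the
branded-drug counts per class (38 units in total).  Published summaries give
only means/SDs, so the distribution shapes (truncated normal, log-normal)
are this module's own choice, made for positivity of the respective
quantities.  Mortality log-OR parameters and approval-year windows are not
part of the published class summaries; the defaults place incretin/SGLT2
classes at mildly protective ORs (log-OR −0.13/−0.16, SD 0.05) and older
classes at null, with year windows from public FDA approval history.

What the generator does **not** emulate: trial-level sampling error,
meta-analytic pooling, correlations between outcomes within a class, or the
actual per-drug values underlying published rankings (those were
hand-extracted from labels and meta-analyses and are not reproducible from
class summaries).  Passing tests on synthetic panels therefore validate the
*model and pipeline*, not any particular published ranking.

## Planted-inefficiency instances

`plant_inefficient_unit` inverts the RDM displacement: given an anchor p on
the frontier and a target θ, the planted value per variable is
v = (p − θ·extreme)/(1 − θ), so the unit displaced by θ along its own range
direction lands exactly on p.  If p lies in the strict interior of an
efficient facet and the planted unit creates no new frontier-relevant extreme
(input/undesirable minimum, desirable maximum), the LP must recover θ
exactly; a vertex anchor only guarantees θ\* ≥ θ.  Validation always rejects
new frontier-relevant extremes; the full [min, max] box is enforced only by
the recovery generator (`enforce_box=True`), so that anchors define every
extreme of the generated instance.

`generate_recovery_instance` places frontier vertices on a strictly concave,
strictly increasing saturating curve y = y0 + s(1 − e^{−k(x−x0)}) (one input,
one desirable output), guaranteeing mutual non-domination under VRS and
making facet-interior anchoring constructive.  Because the planted unit must
stay inside the anchor box, feasible θ is geometrically capped (high-benefit
anchors sit at high input, but large θ needs both low input and high
benefit); the steep-then-flat curve supports θ up to ≈ 0.7, and default
planted θ are drawn from U(0.05, 0.6) with up to 100 anchor redraws per unit.
Recovery holds to 1e−6 (observed ≈ 1e−13) across hundreds of seeded
instances.

## Analysis conventions

- **Ranking**: standard competition ranking on full-precision efficiencies
  (ties share the minimal rank, the next distinct value skips); row order
  breaks ties by unit id.
- **Era comparison**: arithmetic means of efficiency for approval years
  before vs at-or-after the threshold (default 2010, inclusive post).  Units
  without a year are excluded with a warning; an empty era reports NaN, never
  0.  No significance test is attached (none is defined for this design).
- **Slack summary** counts the largest-normalised-slack variable per unit;
  units whose slacks are all zero are excluded, so counts sum to the number
  of units with a nonzero slack.

## Problem sizes

Default verification sizes were chosen so the full suite and the
reproduction script run comfortably on a single CPU: 200 oracle instances at
500 grid subdivisions (n ≤ 4; coarser grids cover n = 5, 6), 50 panels for
each invariance sweep, ≥ 1000 units for boundedness, 100 recovery instances,
and a 38-unit synthetic panel for the pipeline metrics.

## Known limitations

- Reference sets depend on the optimal basis chosen by the solver; with
  degenerate frontiers, different but equally valid decompositions exist.
- Raw phase-II slacks of zero-range variables are not in the objective and
  take whatever value the optimal vertex implies; only normalised slacks
  (defined 0 there) should be compared across variables.
- The grid oracle's accuracy guarantee degrades when a unit's ranges are
  tiny relative to the panel's spread (large effective Lipschitz constant);
  it is a testing device, not a production solver.
- Era means are descriptive; with few units per era they carry large
  sampling variability.
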