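# medeff

Medication-efficiency benchmarking for drugs with multidimensional benefits
and harms, built on the **range directional model (RDM)**, a data envelopment
analysis (DEA) variant that stays well defined when outcomes are negative
(weight *gain*) and when some outcomes are undesirable (mortality).

The motivating application is type-2-diabetes pharmacotherapy: each drug is a
decision-making unit (DMU) characterised by its dose frequency (input,
doses/day; weekly dosing = 1/7), HbA1c reduction and weight change (desirable
outputs, %; weight loss positive, gain negative), and optionally an all-cause
mortality odds ratio vs placebo (undesirable output, lower better).
*Medication efficiency* is then the benefit-and-harm achieved per dose,
measured against the best frontier that convex combinations of the observed
drugs can span.

## The model

For the evaluated unit *o*, the ranges of possible improvement are

```
R_x[j] = x_oj − min_i x_ij        inputs
R_y[r] = max_i y_ir − y_or        desirable outputs
R_z[f] = z_of − min_i z_if        undesirable outputs (input-like)
```

and the inefficiency score θ\* solves the linear program (variable returns to
scale via the convexity constraint):

```
max θ   s.t.   Σ λ_i x_ij + θ R_x[j] ≤ x_oj     j = 1..m
               Σ λ_i y_ir − θ R_y[r] ≥ y_or     r = 1..s
               Σ λ_i z_if + θ R_z[f] ≤ z_of     f = 1..h
               Σ λ_i = 1,   λ ≥ 0,   0 ≤ θ ≤ 1
```

Efficiency is **1 − θ\*** ∈ [0, 1]; frontier drugs score 1.  Because the
direction is the unit's own range, θ\* is invariant to translating any output
column and to rescaling any variable column — the properties that make the
score meaningful for mixed-sign, mixed-unit clinical data.  A second LP phase
fixes θ = θ\* and maximises range-normalised residual slacks, identifying
*which* variable (dosing burden, glycaemic effect, weight effect, mortality)
keeps a drug off the frontier.

The package also ships a simplex-grid brute-force oracle (`brute_force_theta`)
that approximates θ\* without linear programming, downstream analyses
(competition ranking with ties, pre/post-era mean comparison, slack tallies,
efficiency timeline), a synthetic generator reproducing the class-level
structure of marketed diabetes drugs, and planted-inefficiency instances with
exactly known θ for end-to-end verification.

## Worked example

```python
from medeff import (Panel, Role, UnitProfile, Variable, VariableSchema,
                    evaluate_all, compute_slacks, reference_weights, solve_rdm)

schema = VariableSchema([
    Variable("dose_frequency", Role.INPUT, "per day"),
    Variable("hba1c_reduction", Role.DESIRABLE, "%"),
])
panel = Panel(schema, [
    UnitProfile("drug_a", {"dose_frequency": 1.0, "hba1c_reduction": 2.0}),
    UnitProfile("drug_b", {"dose_frequency": 2.0, "hba1c_reduction": 4.0}),
    UnitProfile("drug_c", {"dose_frequency": 2.0, "hba1c_reduction": 2.0}),
])
for r in evaluate_all(panel):
    print(f"{r.unit_id}: theta*={r.theta_star:.3f}  efficiency={r.efficiency:.3f}  "
          f"references={reference_weights(r, 0.01)}")
```

prints

```
drug_a: theta*=0.000  efficiency=1.000  references={'drug_a': 1.0}
drug_b: theta*=0.000  efficiency=1.000  references={'drug_b': 1.0}
drug_c: theta*=0.500  efficiency=0.500  references={'drug_a': 0.5, 'drug_b': 0.5}
```

`drug_a` and `drug_b` span the frontier.  `drug_c` delivers `drug_b`'s dosing
burden with `drug_a`'s benefit, so it can move half of its maximal possible
improvement in every direction before hitting the frontier: θ\* = 0.5,
efficiency 0.5, benchmarked against the equal-weight mix of the two frontier
drugs.  Its phase-II slacks are zero — the projection lands exactly on the
frontier facet, so neither variable is singled out as the bottleneck.

## Command line

```sh
medeff simulate --seed 42 --output-dir out          # synthetic drug panel CSV
medeff rank        --input out/panel.csv --output-dir out
medeff slacks      --input out/panel.csv --output-dir out
medeff era-compare --input out/panel.csv --output-dir out --threshold-year 2010
```

Outputs are deterministic CSVs (`results.csv`, `ranking.csv`, `slacks.csv`,
`era.csv`); `--config` takes a YAML file declaring each column's role for
non-default layouts.  Exit codes: 2 for validation errors, 3 for solver
failures.

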