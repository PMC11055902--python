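# Methods

## Model

The package implements the fuzzy difference equation

```
x_{n+1} = A + B x_n + x_n / (x_{n-1} x_{n-2})
```

for positive fuzzy `A`, `B`, `x_{-2}`, `x_{-1}`, `x_0`. A fuzzy quantity is
represented by its α-cuts `[L(α), R(α)]` on a shared grid of membership
levels; all arithmetic is levelwise interval arithmetic, vectorized over the
grid. `A` plays the role of an additive process-error level, `B` of a
threshold-density coefficient; the delayed product `x_{n-1} x_{n-2}` in the
denominator makes growth self-limiting at high recent densities and
amplifying at low ones.

Taking α-cuts of the recursion requires dividing the interval `[x_n]_α` by
the positive product interval. Two divisions are supported:

* **g-division** (the default): the quotient `W` defined by `H = P·W`
  (Case I) or `P = H·W⁻¹` (Case II). For positive intervals this gives
  same-side endpoint quotients in Case I (`[H_l/P_l, H_r/P_r]`) and
  cross-assigned quotients in Case II (`[H_r/P_r, H_l/P_l]`). Which case
  applies is decided by the sign of `H_l P_r − H_r P_l`, which must be
  uniform across levels.
* **Zadeh extension-principle division**: `[H_l/P_r, H_r/P_l]`. Always at
  least as wide as the g-quotient; kept for comparison runs.

Under Case I the endpoint recursions decouple: each of `L(α)` and `R(α)`
independently follows the crisp map `y' = p + a y + y/(y₁ y₂)` with
`(p, a)` the matching endpoints of `(A, B)`. Under Case II the quotient term
cross-couples them, giving the planar system `y' = p + a y + z/(z₁ z₂)`,
`z' = q + b z + y/(y₁ y₂)` per level with `(p, a, q, b) = (A_l, B_l, A_r,
B_r)`.

## Equilibria and stability

All equilibria are closed-form; constructors assert the fixed-point residual
is below 1e-12 (relative):

* crisp / Case-I endpoints: `ȳ = (p + √(p² + 4(1−a))) / (2(1−a))`, requiring
  `B < 1` at the relevant endpoint;
* Case-II endpoint pair: the positive root pair of `y = p + a y + 1/z`,
  `z = q + b z + 1/y`.

Stability machinery:

* the Case-I linearization coefficient
  `G = 2(1−a)² / (p² + 2(1−a) + p√(p² + 4(1−a)))`, with asymptotic stability
  iff `6(1−a)` over the same denominator is below 1 (equivalent to
  `3p² > 4(1−a)`, which the tests cross-check against the closed inequality
  on random parameters);
* for the coupled system, a weighted ∞-norm certificate: the 6×6 Jacobian `T`
  at the equilibrium is conjugated by `diag(1, ε, …, ε⁵)` with ε taken (by
  default) as the midpoint of the admissible interval
  `( ((1−b)/(1−a)·p²/q²)^{1/6}, 1 )`; the report carries the interval, the ε
  used, the norm, and the stable flag. The conjugation uses positive powers
  of ε: that is the scaling under which the shifted-coordinate rows have sum
  ε < 1 and the norm certificate can close (the negative-power variant makes
  the norm exceed 1 even on parameter sets that are demonstrably stable, so
  it cannot be the intended weight).

Literal condition checkers are provided for each boundedness/convergence
condition set (`check_conditions`). Two deliberate reading choices, both
surfaced in the reports rather than silently applied:

* the Case-I statements' bounded-parameter condition is printed as
  `A_{r,0} < 1`, which contradicts their own requirement that A exceed 1 and
  fails on the package's reference scenario; the literal form is evaluated by
  default and an `alternate_reading=True` flag substitutes `B_{r,0} < 1`;
* strict inequalities that compare a left-endpoint quantity against the
  corresponding right-endpoint quantity degenerate to `x < x` at α = 1,
  where the two cuts coincide; exact ties are therefore not counted as
  violations, otherwise every such condition would be vacuously false for
  every genuine fuzzy scenario.

## Case classification and forced-case runs

`classify_case` labels a state Case I if the classification product
difference is ≤ 0 at every level and Case II if ≥ 0 at every level; exact
ties (always present at the crisp core) are compatible with either branch,
and an all-tie state — e.g. fully crisp data — is labelled Case I. A genuine
sign change across levels raises a diagnostic error listing the offending
levels; `g_divide` exposes an `allow_mixed` escape hatch that switches branch
per level but may return a non-canonical (improper) result.

`simulate` validates every iterate (nested, positive endpoints). In `auto`
and `zadeh` modes an invalid iterate raises. In forced-case modes it is
recorded per step (`Trajectory.proper`) instead: forcing a case against the
state's actual classification applies the endpoint recursions *formally*,
and on the reference scenario the forced Case-I run transiently crosses its
endpoints (steps 2–4) before the decoupled endpoint recursions converge and
restore the ordering. Aborting there would make the forced-case analyses —
whose long-run limits are exactly the closed-form fuzzy equilibria —
unreproducible, so tolerated-but-flagged is the deliberate behaviour.

Iterates above 1e12 set a divergence flag and stop the run; parameter
regions outside the stability conditions (e.g. `B ≥ 1`) genuinely diverge.

## Default parameters and the scenario generator

The α grid defaults to 101 uniform levels including 0 (support) and 1
(core); the quartile levels used by the reference tables lie exactly on it,
and parabolic endpoints are evaluated exactly at any level from their
`(center, spread)` spec, so table output does not depend on grid
interpolation.

The reference scenario uses symmetric parabolic fuzzy numbers
(membership `1 − ((x−c)/s)²`, α-cut `[c − s√(1−α), c + s√(1−α)]`):
`A = (1.75, 0.25)`, `B = (0.25, 0.1)`, initial sizes centered at 1 unit with
spreads 0.25/0.35/0.45 (growing fuzziness toward the most recent
generation). These are the study conditions throughout the tests and the
acceptance script.

`random_scenario` rejection-samples parabolic `(center, spread)` tuples until
the named condition set passes (or, for the `unstable` regime, until both
convergence-region sets fail), deterministically per seed. The sampling
boxes are chosen so each regime is reachable with acceptance probability of
order one: the Case-I region needs `A` below 1 with `B` large enough that
`3A² > 4(1−B)` (centers 0.72–0.95 and 0.70–0.93, spreads ≤ 0.04), the
Case-II region `A` comfortably above 1 with moderate `B` (centers 1.3–2.2
and 0.15–0.5).

What the generator emulates — and does not: scenarios are always symmetric
parabolic fuzzy numbers with point cores, the family the model's worked
analysis uses. Real survey uncertainty need not be symmetric, unimodal, or
parabolic, and real parameters drift over time; passing tests therefore
demonstrate the arithmetic and the dynamics on this family, not robustness
to arbitrary membership shapes or nonstationary data.

## Numerical choices

* Endpoint comparisons (monotonicity, ordering, case ties) use an absolute
  slack of 1e-12; fixed-point residuals must be ≤ 1e-12 relative.
* The metric `D` is the grid maximum of the endpoint discrepancies — exact
  whenever the extrema sit on the grid, which holds for parabolic families
  (maximum spread at α = 0).
* The sup-min division oracle samples each support uniformly (core points
  appended so membership-1 pairs exist exactly), reconstructs membership by
  linear interpolation in α along the two endpoint branches, and reads each
  α-cut as the extrema of quotients whose pair membership reaches that
  level; agreement with the levelwise quotient is O(1/n_samples) with the
  first-order error constant `(w_H + q·w_P)/P_l`.
* No rounding occurs inside recursions; the half-up 4-decimal rounding used
  for tables is applied only at reporting (`round_half_up`).
* Simulation sizes in the test suite: convergence runs are capped at 10⁴
  steps with early stopping once `D < 1e-6` (all reference runs converge
  within ~50 steps; the random-regime sweeps within a few hundred), and the
  property sweeps use 50 scenarios per stability regime on the full
  101-level grid.

## Known limitations

* Only positive fuzzy numbers with interval α-cuts are supported; no
  gH-difference, no zero/negative supports in model inputs.
* The generalized family `x' = A + Bx + Cx/(D + Π x_{n−k}^{p_k})` is
  simulated crisp-only; its fuzzy theory is out of scope.
* The boundedness-table column depends on a choice of the `y₃` anchor
  (initial value vs. third iterate); the table reproduction uses the
  initial-value endpoints (`x_{-2,l}` left, `x_{0,r}` right) and reports the
  column without asserting it.
* Mid-trajectory case switching is permitted in `auto` mode; the closed-form
  convergence statements apply to the forced single-case recursions.
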