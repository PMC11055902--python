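# fbqp — a fuzzy Bobwhite-quail population model under g-division

`fbqp` simulates and analyses the third-order rational difference equation

```
x_{n+1} = A + B x_n + x_n / (x_{n-1} x_{n-2}),      n = 0, 1, ...
```

in which the parameters and the three initial population sizes are **positive
fuzzy numbers** rather than reals. `A` absorbs the (log) process-error level
of the population survey, `B` indexes the threshold density, and the
two-generation product in the denominator encodes delayed density dependence.
The fuzziness represents survey/measurement vagueness: each quantity is an
α-cut family of nested intervals `[L(α), R(α)]`, α ∈ [0, 1], with the α = 1
cut the crisp "best estimate" and the α = 0 cut the full support.

The package is for researchers in theoretical ecology and fuzzy dynamical
systems who want a concrete, tested implementation of α-cut interval
recursions under **generalized (g-)division** — the division defined by the
multiplicative identities `H = P·W` (Case I) or `P = H·W⁻¹` (Case II), which
yields strictly narrower quotients than the classical Zadeh
extension-principle division and therefore less ambiguity inflation along a
trajectory.

## What it computes

* **Fuzzy arithmetic** (`fbqp.fuzzy`): parabolic and crisp fuzzy numbers on a
  shared α grid; addition, scaling, positive multiplication, g-division with
  Case I/II classification, Zadeh division, the sup-metric `D`, a brute-force
  sup-min division oracle, and validation of the nested-interval structure.
* **Dynamics** (`fbqp.model`): per-level endpoint recursions. Under Case I
  the left/right endpoints decouple into two copies of the crisp recursion
  `y' = p + a y + y/(y₁y₂)`; under Case II the quotient term cross-couples
  them. Modes: per-step automatic case classification, forced Case I/II, and
  Zadeh division for comparison. Crisp, coupled, and generalized-family
  reference recursions are included.
* **Equilibria and stability** (`fbqp.stability`): closed forms for the crisp
  equilibrium `(p + √(p² + 4(1−a)))/(2(1−a))`, the coupled Case-II pair, and
  both fuzzy equilibria per α-cut; boundedness/persistence envelopes; the
  linearization coefficient `G`; a weighted-∞-norm Jacobian stability check
  for the coupled system; and literal checkers for every stability condition
  set, with an explicit flag for one alternate reading (see
  `docs/methods.md`).
* **Scenarios and tooling** (`fbqp.scenarios`, `fbqp.cli`): the reference
  parabolic scenario, seeded rejection sampling of scenarios inside (or
  outside) the stability regions, table reproduction, g-vs-Zadeh comparison,
  and a multistart eventual-stability demonstration.

## Worked example

```python
from fbqp import *

scenario = reference_scenario()            # parabolic A, B and initial sizes
eq = fuzzy_equilibrium_case2(scenario.A, scenario.B)
print("support of the Case-II fuzzy equilibrium:", [round(v, 4) for v in eq.cut(0.0)])
print("crisp (alpha=1) equilibrium:             ", round(eq.cut(1.0)[0], 4))

traj = simulate(scenario, 100, mode="auto", ref=eq.as_fuzzy())
print("g-division case selected at every step:", traj.cases[-1])
print("D(x_n, x*) at steps 10/50/100:",
      [f"{traj.distances[i + 2]:.2e}" for i in (10, 50, 100)])

comp = compare_division(scenario, n_steps=60)
print("terminal support width, g-division:", round(comp.terminal_g.width[0], 4))
print("terminal support width, Zadeh:     ", round(comp.terminal_zadeh.width[0], 4))
```

prints

```
support of the Case-II fuzzy equilibrium: [2.0728, 3.8192]
crisp (alpha=1) equilibrium:              2.8081
g-division case selected at every step: CaseLabel.CASE_II
D(x_n, x*) at steps 10/50/100: ['7.12e-02', '4.65e-10', '1.33e-15']
terminal support width, g-division: 1.7464
terminal support width, Zadeh:      3.8529
```

Reading: with A centered at 1.75 (half-width 0.25) and B centered at 0.25
(half-width 0.1), the population settles — from *any* positive start — onto a
fixed fuzzy level whose plausible range is about 2.07–3.82 population units
with best estimate 2.8081. The automatic classifier selects the Case-II
endpoint recursion at every step for these initial data, convergence in the
sup-metric `D` is geometric, and g-division keeps the terminal uncertainty
band less than half as wide as extension-principle division would. Because
every start converges to the same attractor, the model exhibits no critical
lower population threshold (no Allee effect).

The same runs are available from the shell:

```sh
fbqp table --case case2 --out out/
fbqp simulate --mode auto --steps 100 --out out/
fbqp compare-division --steps 60 --out out/
fbqp multistart --starts 0.5,1,2,4 --out out/
```

## Layout

```
src/fbqp/fuzzy.py       alpha-cut fuzzy numbers and their arithmetic
src/fbqp/model.py       fuzzy / crisp / coupled / generalized recursions
src/fbqp/stability.py   equilibria, bounds, linearized stability, condition checkers
src/fbqp/scenarios.py   reference + random scenarios, tables, comparisons
src/fbqp/cli.py         click CLI (`fbqp ...`)
docs/methods.md         model assumptions, numerical choices, limitations
```
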