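"""Iteration of the fuzzy Bobwhite-quail recursion and its crisp references.

The model is ``x_{n+1} = A + B x_n + x_n / (x_{n-1} x_{n-2})`` with positive
fuzzy parameters A (process-error level) and B (threshold-density index) and
three fuzzy initial population sizes.  Taking alpha-cuts and dividing by
g-division yields one of two endpoint recursions per level:

* Case I  — left and right endpoints decouple; each independently satisfies
  the crisp recursion.
* Case II — the quotient term cross-couples the endpoints (the left endpoint
  receives the right-endpoint quotient and vice versa).

``simulate`` can re-classify the case at every step (``auto``), force one
branch throughout (matching the closed-form analyses), or replace the quotient
with extension-principle division (``zadeh``) for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fuzzy import (
    AlphaGrid,
    CaseLabel,
    FuzzyNumber,
    MixedCaseError,
    add,
    metric_D,
    multiply,
    validate,
    zadeh_divide,
    _TIE_TOL,
)

__all__ = [
    "Scenario",
    "CrispParams",
    "GFBQPParams",
    "Trajectory",
    "InvalidIterateError",
    "classify_case",
    "step",
    "simulate",
    "simulate_crisp",
    "simulate_coupled_case2",
    "simulate_gfbqp_crisp",
    "trajectory_distance",
    "DIVERGENCE_THRESHOLD",
]

#: iterates beyond this magnitude flag the run as divergent and stop it
DIVERGENCE_THRESHOLD = 1e12

Mode = Literal["auto", "force_case1", "force_case2", "zadeh"]


class InvalidIterateError(ValueError):
    """An iterate failed the nested-interval validation."""


@dataclass(frozen=True)
class Scenario:
    """Fuzzy parameters A, B and initial values (x_{-2}, x_{-1}, x_0).

    ``specs`` optionally records the (family, center, spread) description of
    each member so exact alpha-cuts can be evaluated off-grid (table output).
    """

    A: FuzzyNumber
    B: FuzzyNumber
    x_init: tuple[FuzzyNumber, FuzzyNumber, FuzzyNumber]
    specs: dict = field(default_factory=dict)

    def __post_init__(self):
        members = {"A": self.A, "B": self.B}
        for name, x in zip(("x_m2", "x_m1", "x_0"), self.x_init):
            members[name] = x
        grid = self.A.grid
        for name, f in members.items():
            if f.grid != grid:
                raise ValueError(f"{name} does not share the scenario grid")
            rep = validate(f, require_positive=True)
            if not rep.valid:
                raise ValueError(f"{name} is not a valid positive fuzzy number: {rep.issues}")

    @property
    def grid(self) -> AlphaGrid:
        return self.A.grid


@dataclass(frozen=True)
class CrispParams:
    """Parameters of the crisp recursion(s): y' = p + a y + quotient.

    ``q``/``b`` parameterize the second component of the coupled Case-II
    system; they default to ``p``/``a`` (symmetric system).
    """

    p: float
    a: float
    q: float | None = None
    b: float | None = None

    def __post_init__(self):
        if self.p <= 0 or self.a < 0:
            raise ValueError("require p > 0 and a >= 0")
        if (self.q is None) != (self.b is None):
            raise ValueError("q and b must be given together")
        if self.q is not None and (self.q <= 0 or self.b < 0):
            raise ValueError("require q > 0 and b >= 0")


@dataclass(frozen=True)
class GFBQPParams:
    """Generalized crisp family x' = A + B x + C x / (D + prod_k x_{n-k}^{p_k})."""

    A: float
    B: float
    C: float
    D: float
    exponents: tuple[float, ...]

    def __post_init__(self):
        if self.C <= 0 or any(p <= 0 for p in self.exponents):
            raise ValueError("require C > 0 and positive exponents")
        if self.A < 0 or self.B < 0 or self.D < 0:
            raise ValueError("require A, B, D >= 0")

    @property
    def m(self) -> int:
        return len(self.exponents)


@dataclass
class Trajectory:
    """Per-step fuzzy iterates with the g-division case used at each step.

    ``indices`` run contiguously from -2 (the three initial values carry no
    case label).  ``distances`` holds D(x_n, ref) when a reference was set.
    """

    grid: AlphaGrid
    indices: list[int]
    values: list[FuzzyNumber]
    cases: list[CaseLabel | str | None]
    proper: list[bool] = field(default_factory=list)
    diverged: bool = False
    distances: list[float] | None = None

    def __len__(self) -> int:
        return len(self.values)

    @property
    def final(self) -> FuzzyNumber:
        return self.values[-1]

    def crisp_slice(self, alpha: float = 1.0) -> np.ndarray:
        """Midpoints of the alpha-cut at the given level along the run."""
        i = self.grid.index_of(alpha)
        return np.array([(x.left[i] + x.right[i]) / 2 for x in self.values])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (step, alpha level)."""
        rows = []
        for n, x, case in zip(self.indices, self.values, self.cases):
            label = case.value if isinstance(case, CaseLabel) else (case or "")
            for a, lo, hi in zip(self.grid.levels, x.left, x.right):
                rows.append((n, a, lo, hi, label))
        return pd.DataFrame(rows, columns=["step", "alpha", "left", "right", "case"])


def classify_case(
    x_n: FuzzyNumber, x_nm1: FuzzyNumber, x_nm2: FuzzyNumber
) -> CaseLabel:
    """Classify which g-division branch the quotient x_n/(x_{n-1}x_{n-2}) takes.

    Case I iff ``x_{n,l} x_{n-1,r} x_{n-2,r} <= x_{n,r} x_{n-1,l} x_{n-2,l}``
    at every level, Case II for the reverse inequality.  Tie levels (equality,
    e.g. the crisp core) are compatible with both branches; an all-tie state
    classifies as Case I.  A genuine sign change raises
    :class:`~fbqp.fuzzy.MixedCaseError`.
    """
    for f in (x_n, x_nm1, x_nm2):
        if not f.is_positive:
            raise ValueError("classification requires positive fuzzy numbers")
    d = x_n.left * x_nm1.right * x_nm2.right - x_n.right * x_nm1.left * x_nm2.left
    if np.all(d <= _TIE_TOL):
        return CaseLabel.CASE_I
    if np.all(d >= -_TIE_TOL):
        return CaseLabel.CASE_II
    pos = x_n.grid.levels[d > _TIE_TOL]
    neg = x_n.grid.levels[d < -_TIE_TOL]
    raise MixedCaseError(
        "case inequality changes sign across alpha levels "
        f"(Case II at {pos[:5]}, Case I at {neg[:5]})",
        np.concatenate([pos, neg]),
    )


def step(
    A: FuzzyNumber,
    B: FuzzyNumber,
    x_n: FuzzyNumber,
    x_nm1: FuzzyNumber,
    x_nm2: FuzzyNumber,
    case: CaseLabel,
    strict: bool = True,
) -> FuzzyNumber:
    """One endpoint-recursion step under the given g-division case.

    With ``strict`` (default) an iterate that is not a proper fuzzy number
    raises :class:`InvalidIterateError`.  ``strict=False`` returns the raw
    endpoint arrays regardless: when a case is *forced* against the state's
    actual classification, the decoupled/cross-coupled recursions are applied
    formally and may transiently cross endpoints before converging.
    """
    L, R = x_n.left, x_n.right
    L1, R1 = x_nm1.left, x_nm1.right
    L2, R2 = x_nm2.left, x_nm2.right
    if np.any(L1 * L2 == 0) or np.any(R1 * R2 == 0):
        raise ZeroDivisionError("zero denominator in the quotient term")
    if case is CaseLabel.CASE_I:
        left = A.left + B.left * L + L / (L1 * L2)
        right = A.right + B.right * R + R / (R1 * R2)
    else:
        left = A.left + B.left * L + R / (R1 * R2)
        right = A.right + B.right * R + L / (L1 * L2)
    out = FuzzyNumber(A.grid, left, right)
    if strict:
        rep = validate(out, require_positive=True)
        if not rep.valid:
            raise InvalidIterateError(f"iterate is not a valid fuzzy number: {rep.issues}")
    return out


def _zadeh_step(A, B, x_n, x_nm1, x_nm2) -> FuzzyNumber:
    # denominator product first, then extension-principle division, then add —
    # matching the term order of the model
    quot = zadeh_divide(x_n, multiply(x_nm1, x_nm2))
    return add(add(A, multiply(B, x_n)), quot)


def simulate(
    s: Scenario,
    n_steps: int,
    mode: Mode = "auto",
    ref: FuzzyNumber | None = None,
    tol: float | None = None,
    strict: bool | None = None,
) -> Trajectory:
    """Iterate the fuzzy model for ``n_steps`` (or until within ``tol`` of ``ref``).

    Modes: ``auto`` re-classifies the g-division case at every step;
    ``force_case1``/``force_case2`` apply one endpoint recursion throughout
    (reproducing the closed-form analyses); ``zadeh`` replaces the quotient
    with extension-principle division.

    Every iterate is validated and its properness recorded in
    ``Trajectory.proper``.  By default an improper iterate raises in ``auto``
    and ``zadeh`` modes (where it would indicate a genuine failure) but is
    tolerated in force modes: forcing a case against the state's actual
    classification applies the endpoint recursions formally, which may cross
    endpoints transiently before the run settles (the ordering is restored as
    the endpoint systems converge).  Iterates beyond
    :data:`DIVERGENCE_THRESHOLD` stop the run with ``diverged=True``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if strict is None:
        strict = mode in ("auto", "zadeh")
    x2, x1, x0 = s.x_init
    traj = Trajectory(
        grid=s.grid,
        indices=[-2, -1, 0],
        values=[x2, x1, x0],
        cases=[None, None, None],
        proper=[True, True, True],
        distances=None if ref is None else [metric_D(x, ref) for x in (x2, x1, x0)],
    )
    for n in range(1, n_steps + 1):
        xn, xm1, xm2 = traj.values[-1], traj.values[-2], traj.values[-3]
        if mode == "zadeh":
            nxt, case = _zadeh_step(s.A, s.B, xn, xm1, xm2), "zadeh"
        else:
            if mode == "auto":
                try:
                    case = classify_case(xn, xm1, xm2)
                except MixedCaseError as err:
                    raise MixedCaseError(f"step {n}: {err}", err.levels) from err
            else:
                case = CaseLabel.CASE_I if mode == "force_case1" else CaseLabel.CASE_II
            nxt = step(s.A, s.B, xn, xm1, xm2, case, strict=False)
        rep = validate(nxt, require_positive=True)
        if strict and not rep.valid:
            raise InvalidIterateError(
                f"step {n}: iterate is not a valid fuzzy number: {rep.issues}"
            )
        traj.indices.append(n)
        traj.values.append(nxt)
        traj.cases.append(case)
        traj.proper.append(rep.valid)
        if ref is not None:
            d = metric_D(nxt, ref)
            traj.distances.append(d)
            if tol is not None and d < tol:
                break
        if float(np.max(nxt.right)) > DIVERGENCE_THRESHOLD:
            traj.diverged = True
            break
    return traj


def simulate_crisp(
    params: CrispParams, y_init: Sequence[float], n_steps: int
) -> np.ndarray:
    """Crisp reference recursion y' = p + a y + y/(y1 y2).

    Returns the full sequence including the three initial values (index 0 is
    y_{-2}).  The run stops early if an iterate exceeds
    :data:`DIVERGENCE_THRESHOLD`, so a shorter-than-requested result signals
    divergence.
    """
    y = list(map(float, y_init))
    if len(y) != 3 or min(y) <= 0:
        raise ValueError("need three positive initial values")
    p, a = params.p, params.a
    for _ in range(n_steps):
        nxt = p + a * y[-1] + y[-1] / (y[-2] * y[-3])
        y.append(nxt)
        if nxt > DIVERGENCE_THRESHOLD:
            break
    return np.asarray(y)


def simulate_coupled_case2(
    params: CrispParams,
    inits: Sequence[tuple[float, float]],
    n_steps: int,
) -> np.ndarray:
    """Cross-coupled crisp system mirroring the Case-II endpoint recursion.

    ``y' = p + a y + z/(z1 z2)`` and ``z' = q + b z + y/(y1 y2)``.  Returns an
    array of shape (len, 2) including the three initial pairs.
    """
    if params.q is None:
        raise ValueError("coupled system needs q and b")
    ys = [float(y) for y, _ in inits]
    zs = [float(z) for _, z in inits]
    if len(ys) != 3 or min(ys + zs) <= 0:
        raise ValueError("need three positive initial pairs")
    p, a, q, b = params.p, params.a, params.q, params.b
    for _ in range(n_steps):
        ny = p + a * ys[-1] + zs[-1] / (zs[-2] * zs[-3])
        nz = q + b * zs[-1] + ys[-1] / (ys[-2] * ys[-3])
        ys.append(ny)
        zs.append(nz)
        if max(ny, nz) > DIVERGENCE_THRESHOLD:
            break
    return np.column_stack([ys, zs])


def simulate_gfbqp_crisp(
    params: GFBQPParams, inits: Sequence[float], n_steps: int
) -> np.ndarray:
    """Crisp simulation of the generalized family (lags 1..m in the product)."""
    m = params.m
    x = list(map(float, inits))
    if len(x) != m + 1 or min(x) <= 0:
        raise ValueError(f"need {m + 1} positive initial values")
    exps = np.asarray(params.exponents)
    for _ in range(n_steps):
        lagged = np.asarray(x[-m - 1:-1][::-1])  # x_{n-1}, ..., x_{n-m}
        denom = params.D + float(np.prod(lagged**exps))
        nxt = params.A + params.B * x[-1] + params.C * x[-1] / denom
        x.append(nxt)
        if nxt > DIVERGENCE_THRESHOLD:
            break
    return np.asarray(x)


def trajectory_distance(t: Trajectory, ref: FuzzyNumber) -> np.ndarray:
    """D(x_n, ref) for every stored iterate."""
    return np.array([metric_D(x, ref) for x in t.values])
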