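"""Closed-form equilibria, boundedness bounds, and stability condition checkers.

All equilibria are closed-form roots of the fixed-point equations, never the
result of root finding; each constructor asserts that the returned value
satisfies its defining equation to 1e-12 relative error.

Case I decouples the alpha-cut endpoints, so each endpoint equilibrium solves
the scalar equation ``y = p + a y + 1/y``.  Case II cross-couples them and the
endpoint pair solves the system ``y = p + a y + 1/z``, ``z = q + b z + 1/y``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .fuzzy import AlphaGrid, FuzzyNumber, validate
from .model import Scenario

__all__ = [
    "EquilibriumResult",
    "ConditionReport",
    "StabilityReport",
    "BoundsResult",
    "crisp_equilibrium_case1",
    "fuzzy_equilibrium_case1",
    "coupled_equilibrium_case2",
    "fuzzy_equilibrium_case2",
    "bound_case1",
    "bounds_case2",
    "linearization_case1",
    "jacobian_case2",
    "check_conditions",
    "CONDITION_SETS",
]

_RESIDUAL_TOL = 1e-12


def _assert_residual(residual: float, scale: float, what: str) -> None:
    if abs(residual) > _RESIDUAL_TOL * max(1.0, abs(scale)):
        raise AssertionError(f"{what}: fixed-point residual {residual:.3e} too large")


@dataclass
class EquilibriumResult:
    """Equilibrium of one of the model's reductions.

    For fuzzy kinds ``left``/``right`` are per-alpha endpoint arrays; for the
    crisp kind both hold the scalar; for the coupled kind they hold (y, z).
    """

    kind: Literal["crisp", "coupled", "fuzzy_case1", "fuzzy_case2"]
    left: np.ndarray
    right: np.ndarray
    grid: AlphaGrid | None = None

    def as_fuzzy(self) -> FuzzyNumber:
        if self.grid is None:
            raise ValueError("not a fuzzy equilibrium")
        return FuzzyNumber(self.grid, self.left, self.right)

    def cut(self, alpha: float) -> tuple[float, float]:
        i = self.grid.index_of(alpha)
        return float(self.left[i]), float(self.right[i])


@dataclass
class ConditionReport:
    """Literal pass/fail of a lemma/theorem condition set, per alpha level."""

    which: str
    conditions: dict  # name -> {"passed": bool array or bool, "value": evaluated quantity}
    overall: bool
    notes: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.overall

    def to_json(self) -> dict:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.bool_, np.floating, np.integer)):
                return v.item()
            return v

        return {
            "which": self.which,
            "overall": self.overall,
            "notes": self.notes,
            "conditions": {
                name: {k: enc(v) for k, v in entry.items()}
                for name, entry in self.conditions.items()
            },
        }


@dataclass
class StabilityReport:
    """Linearized-stability quantities for the crisp (G) or coupled (norm) case."""

    stable: bool
    G: float | None = None
    ratio: float | None = None  # the quantity required to be < 1
    T: np.ndarray | None = None
    epsilon: float | None = None
    epsilon_interval: tuple[float, float] | None = None
    norm: float | None = None


@dataclass
class BoundsResult:
    """Persistence/boundedness constants: all iterates' supports lie in [M, N]."""

    lower: tuple[float, float]
    upper: tuple[float, float]
    c1: float | None = None
    c2: float | None = None


# ---------------------------------------------------------------------------
# Equilibria


def crisp_equilibrium_case1(p: float, a: float) -> float:
    """Positive root of y = p + a y + 1/y, i.e. (p + sqrt(p^2+4(1-a)))/(2(1-a))."""
    if not 0 <= a < 1:
        raise ValueError("require 0 <= a < 1")
    if p <= 0:
        raise ValueError("require p > 0")
    y = (p + math.sqrt(p * p + 4 * (1 - a))) / (2 * (1 - a))
    _assert_residual(y - (p + a * y + 1 / y), y, "crisp equilibrium")
    return y


def fuzzy_equilibrium_case1(A: FuzzyNumber, B: FuzzyNumber) -> EquilibriumResult:
    """Case-I fuzzy equilibrium: each endpoint solves the scalar equation."""
    _require_positive_pair(A, B)
    if np.any(B.right >= 1):
        raise ValueError("Case-I equilibrium needs B_r(alpha) < 1 at every level")
    left = (A.left + np.sqrt(A.left**2 + 4 * (1 - B.left))) / (2 * (1 - B.left))
    right = (A.right + np.sqrt(A.right**2 + 4 * (1 - B.right))) / (2 * (1 - B.right))
    res = EquilibriumResult("fuzzy_case1", left, right, A.grid)
    _validate_fuzzy_eq(res)
    resid = np.max(np.abs(left - (A.left + B.left * left + 1 / left)))
    _assert_residual(resid, float(np.max(left)), "fuzzy Case-I equilibrium (left)")
    resid = np.max(np.abs(right - (A.right + B.right * right + 1 / right)))
    _assert_residual(resid, float(np.max(right)), "fuzzy Case-I equilibrium (right)")
    return res


def coupled_equilibrium_case2(p: float, a: float, q: float, b: float) -> tuple[float, float]:
    """Unique positive equilibrium of y = p + a y + 1/z, z = q + b z + 1/y."""
    if not (0 <= a < 1 and 0 <= b < 1):
        raise ValueError("require 0 <= a, b < 1")
    if p <= 0 or q <= 0:
        raise ValueError("require p, q > 0")
    y = (p * q - (b - a) + math.sqrt((p * q + a - b) ** 2 + 4 * p * q * (1 - a))) / (
        2 * q * (1 - a)
    )
    z = (p * q + (b - a) + math.sqrt((p * q + b - a) ** 2 + 4 * p * q * (1 - b))) / (
        2 * p * (1 - b)
    )
    _assert_residual(y - (p + a * y + 1 / z), y, "coupled equilibrium (y)")
    _assert_residual(z - (q + b * z + 1 / y), z, "coupled equilibrium (z)")
    return y, z


def fuzzy_equilibrium_case2(A: FuzzyNumber, B: FuzzyNumber) -> EquilibriumResult:
    """Case-II fuzzy equilibrium; per level it equals the coupled equilibrium
    with (p, a, q, b) = (A_l, B_l, A_r, B_r)."""
    _require_positive_pair(A, B)
    if np.any(B.right >= 1):
        raise ValueError("Case-II equilibrium needs B_r(alpha) < 1 at every level")
    prod = A.left * A.right
    sl = B.left - B.right + prod
    sr = B.right - B.left + prod
    left = (sl + np.sqrt(sl**2 + 4 * prod * (1 - B.left))) / (2 * A.right * (1 - B.left))
    right = (sr + np.sqrt(sr**2 + 4 * prod * (1 - B.right))) / (2 * A.left * (1 - B.right))
    res = EquilibriumResult("fuzzy_case2", left, right, A.grid)
    _validate_fuzzy_eq(res)
    resid = np.max(np.abs(left - (A.left + B.left * left + 1 / right)))
    _assert_residual(resid, float(np.max(left)), "fuzzy Case-II equilibrium (left)")
    resid = np.max(np.abs(right - (A.right + B.right * right + 1 / left)))
    _assert_residual(resid, float(np.max(right)), "fuzzy Case-II equilibrium (right)")
    return res


def _require_positive_pair(A: FuzzyNumber, B: FuzzyNumber) -> None:
    if A.grid != B.grid:
        raise ValueError("A and B live on different alpha grids")
    if not (A.is_positive and B.is_positive):
        raise ValueError("A and B must be positive fuzzy numbers")


def _validate_fuzzy_eq(res: EquilibriumResult) -> None:
    if np.any(res.left <= 0):
        raise ValueError("equilibrium endpoints must be positive")
    rep = validate(res.as_fuzzy())
    if not rep.valid:
        raise ValueError(f"equilibrium is not a proper fuzzy number: {rep.issues}")


# ---------------------------------------------------------------------------
# Bounds


def bound_case1(p: float, a: float, y3: float) -> tuple[float, float]:
    """Envelope p < y_n < p^3/((1-a)p^2 - 1) + y_3 for the crisp recursion.

    Requires 0 < a < 1 and (1-a)p^2 > 1.  ``y3`` is caller-supplied: the bound
    holds with the third iterate, but table reproductions may substitute an
    initial value (the printed bounds are consistent with several choices).
    """
    if not 0 < a < 1:
        raise ValueError("require 0 < a < 1")
    if (1 - a) * p * p <= 1:
        raise ValueError("require (1-a) p^2 > 1")
    return p, p**3 / ((1 - a) * p * p - 1) + y3


def bounds_case2(
    p: float, a: float, q: float, b: float, y2: float, z2: float
) -> BoundsResult:
    """Boundedness constants for the coupled Case-II system.

    c1 = p + (1+b)/q + (1+a)/(q^2 p) + 1/(q^3 p^2), c2 symmetric under
    (p,a) <-> (q,b); then p <= y_n <= c1/(1-a) + y2 and likewise for z.
    """
    if not (0 < a < 1 and 0 < b < 1):
        raise ValueError("require 0 < a, b < 1")
    if p <= 0 or q <= 0:
        raise ValueError("require p, q > 0")
    c1 = p + (1 + b) / q + (1 + a) / (q * q * p) + 1 / (q**3 * p * p)
    c2 = q + (1 + a) / p + (1 + b) / (p * p * q) + 1 / (p**3 * q * q)
    return BoundsResult(
        lower=(p, q),
        upper=(c1 / (1 - a) + y2, c2 / (1 - b) + z2),
        c1=c1,
        c2=c2,
    )


# ---------------------------------------------------------------------------
# Linearized stability


def linearization_case1(p: float, a: float) -> StabilityReport:
    """Linearization about the Case-I equilibrium.

    The linearized recursion is ``y' - (a+G) y + G y1 + G y2 = 0`` with
    G = 2(1-a)^2 / (p^2 + 2(1-a) + p sqrt(p^2+4(1-a))); asymptotic stability
    holds when 6(1-a)/denominator < 1 (equivalently 3p^2 > 4(1-a)).
    """
    if not 0 < a < 1:
        raise ValueError("require 0 < a < 1")
    if p <= 0:
        raise ValueError("require p > 0")
    denom = p * p + 2 * (1 - a) + p * math.sqrt(p * p + 4 * (1 - a))
    G = 2 * (1 - a) ** 2 / denom
    ratio = 6 * (1 - a) / denom
    return StabilityReport(stable=ratio < 1, G=G, ratio=ratio)


def jacobian_case2(
    p: float, a: float, q: float, b: float, epsilon: float | None = None
) -> StabilityReport:
    """Weighted-norm stability check for the coupled Case-II system.

    Builds the 6x6 Jacobian T of the coupled system at its equilibrium,
    conjugates by G = diag(1, e^-1, ..., e^-5) with e chosen in
    ( ((1-b)/(1-a) p^2/q^2)^(1/6), 1 ) — midpoint by default — and reports the
    infinity norm of G T G^{-1}; stability requires the norm < 1.
    """
    if not (0 < a < 1 and 0 < b < 1):
        raise ValueError("require 0 < a, b < 1")
    lo = (((1 - b) / (1 - a)) * p * p / (q * q)) ** (1 / 6)
    if lo >= 1:
        raise ValueError(
            "condition p^2/(1-a) < q^2/(1-b) fails: the weight interval is empty"
        )
    if epsilon is None:
        epsilon = (lo + 1) / 2
    if not lo < epsilon < 1:
        raise ValueError(f"epsilon must lie in ({lo}, 1)")
    y, z = coupled_equilibrium_case2(p, a, q, b)
    iy2, iz2 = 1 / (y * y), 1 / (z * z)
    T = np.array(
        [
            [a, 0, 0, iz2, -iz2, -iz2],
            [1, 0, 0, 0, 0, 0],
            [0, 1, 0, 0, 0, 0],
            [iy2, -iy2, -iy2, b, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 0, 0, 0, 1, 0],
        ]
    )
    # weight diag(1, e, e^2, ..., e^5): the scaling that sends the delayed
    # coordinates' unit entries to e < 1 and makes the infinity norm certify
    # stability on the admissible interval
    G = np.diag(epsilon ** np.arange(6.0))
    L = G @ T @ np.linalg.inv(G)
    norm = float(np.linalg.norm(L, np.inf))
    return StabilityReport(
        stable=norm < 1,
        T=T,
        epsilon=epsilon,
        epsilon_interval=(lo, 1.0),
        norm=norm,
    )


# ---------------------------------------------------------------------------
# Condition checkers

CONDITION_SETS = ("case1_bounded", "case1_convergence", "case2_bounded", "case2_convergence", "crisp_envelope", "crisp_convergence", "coupled_convergence")


def check_conditions(
    s: Scenario, which: str, alternate_reading: bool = False
) -> ConditionReport:
    """Evaluate a theorem/lemma parameter-condition set literally, per level.

    The state-dependent case inequality that accompanies the fuzzy theorems is
    a property of a trajectory step (see :func:`fbqp.model.classify_case`) and
    is not evaluated here.

    ``alternate_reading`` replaces the bounded-parameter condition
    ``A_{r,0} < 1`` of the Case-I statements with ``B_{r,0} < 1``.  The
    literal condition contradicts the statements' other requirements (which
    force A > 1) and fails on the source's own worked example, so the
    alternate reading is offered explicitly; reports always say which reading
    was used.
    """
    if which not in CONDITION_SETS:
        raise ValueError(f"unknown condition set {which!r}; one of {CONDITION_SETS}")
    Al, Ar = s.A.left, s.A.right
    Bl, Br = s.B.left, s.B.right
    conds: dict[str, dict] = {}
    notes: list[str] = []

    def cond(name, passed, value):
        conds[name] = {"passed": np.asarray(passed), "value": np.asarray(value)}

    def lt(x, y):
        # strict "<" between left- and right-endpoint quantities; at the crisp
        # core (alpha=1) the two sides coincide identically, so exact ties are
        # not counted as violations (a strict reading would be vacuous)
        return (x < y) | (np.abs(x - y) <= 1e-12)

    if which in ("case1_bounded", "case1_convergence"):
        if alternate_reading:
            cond("B_r0 < 1 (alternate reading)", Br[0] < 1, Br[0])
            notes.append("bounded-parameter condition read as B_{r,0} < 1")
        else:
            cond("A_r <= A_r0 < 1 (literal)", (Ar <= Ar[0]) & (Ar[0] < 1), Ar)
            notes.append(
                "literal condition A_{r,0} < 1 contradicts the A > 1 the other "
                "conditions require; pass alternate_reading=True for B_{r,0} < 1"
            )
    if which == "case1_bounded":
        cond("(1-B_l) A_l^2 > 1", (1 - Bl) * Al**2 > 1, (1 - Bl) * Al**2)
        cond("(1-B_r) A_r^2 > 1", (1 - Br) * Ar**2 > 1, (1 - Br) * Ar**2)
    elif which == "case1_convergence":
        cond(
            "A_r B_l - A_l B_r < A_r - A_l",
            lt(Ar * Bl - Al * Br, Ar - Al),
            Ar * Bl - Al * Br - (Ar - Al),
        )
        cond("3 A_l^2 > 4(1-B_l)", 3 * Al**2 > 4 * (1 - Bl), 3 * Al**2 - 4 * (1 - Bl))
        cond("3 A_r^2 > 4(1-B_r)", 3 * Ar**2 > 4 * (1 - Br), 3 * Ar**2 - 4 * (1 - Br))
    elif which == "case2_bounded":
        cond("B_r <= B_r0 < 1", (Br <= Br[0]) & (Br[0] < 1), Br)
    elif which == "case2_convergence":
        cond("B_r <= B_r0 < 1", (Br <= Br[0]) & (Br[0] < 1), Br)
        cond(
            "(1-B_r) A_l^2 < (1-B_l) A_r^2",
            lt((1 - Br) * Al**2, (1 - Bl) * Ar**2),
            (1 - Bl) * Ar**2 - (1 - Br) * Al**2,
        )
        cond(
            "1 < (1-B_l)(1-B_r) A_l^2 A_r^2",
            (1 - Bl) * (1 - Br) * Al**2 * Ar**2 > 1,
            (1 - Bl) * (1 - Br) * Al**2 * Ar**2,
        )
    elif which == "crisp_envelope":
        # per endpoint: 0 < a < 1 and (1-a) p^2 > 1 with (p, a) = (A, B) cuts
        cond("0 < B < 1", (Bl > 0) & (Br < 1), np.column_stack([Bl, Br]))
        cond("(1-B_l) A_l^2 > 1", (1 - Bl) * Al**2 > 1, (1 - Bl) * Al**2)
        cond("(1-B_r) A_r^2 > 1", (1 - Br) * Ar**2 > 1, (1 - Br) * Ar**2)
    elif which == "crisp_convergence":
        cond("0 < B < 1", (Bl > 0) & (Br < 1), np.column_stack([Bl, Br]))
        cond("3 A_l^2 > 4(1-B_l)", 3 * Al**2 > 4 * (1 - Bl), 3 * Al**2 - 4 * (1 - Bl))
        cond("3 A_r^2 > 4(1-B_r)", 3 * Ar**2 > 4 * (1 - Br), 3 * Ar**2 - 4 * (1 - Br))
    elif which == "coupled_convergence":
        # coupled system parameters (p, a, q, b) = (A_l, B_l, A_r, B_r)
        cond("0 < B < 1", (Bl > 0) & (Br < 1), np.column_stack([Bl, Br]))
        cond(
            "(1-B_r) A_l^2 < (1-B_l) A_r^2",
            lt((1 - Br) * Al**2, (1 - Bl) * Ar**2),
            (1 - Bl) * Ar**2 - (1 - Br) * Al**2,
        )
        cond(
            "1 < (1-B_l)(1-B_r) A_l^2 A_r^2",
            (1 - Bl) * (1 - Br) * Al**2 * Ar**2 > 1,
            (1 - Bl) * (1 - Br) * Al**2 * Ar**2,
        )

    overall = all(bool(np.all(entry["passed"])) for entry in conds.values())
    return ConditionReport(which=which, conditions=conds, overall=overall, notes=notes)
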