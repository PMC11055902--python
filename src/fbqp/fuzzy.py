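"""Positive fuzzy numbers as alpha-cut families, with the arithmetic the model needs.

A fuzzy number is stored as a pair of endpoint arrays ``left``/``right`` over a
shared grid of membership levels alpha in [0, 1].  The alpha-cut at level
``alpha`` is the closed interval ``[left(alpha), right(alpha)]``; the alpha=0
entry holds the support endpoints (closure of the union of the positive cuts).

Two divisions are provided:

* :func:`g_divide` — generalized division, defined by the multiplicative
  identities ``H = P * W`` (Case I) or ``P = H * W^{-1}`` (Case II).  It yields
  the narrowest proper fuzzy quotient and is the division the population model
  uses.
* :func:`zadeh_divide` — the classical extension-principle division,
  ``[H_l/P_r, H_r/P_l]`` per level, kept for comparison; it is never narrower
  than g-division.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AlphaGrid",
    "FuzzyNumber",
    "ParabolicSpec",
    "CaseLabel",
    "ValidationReport",
    "MixedCaseError",
    "ImproperResultError",
    "make_parabolic",
    "make_crisp",
    "add",
    "scale",
    "multiply",
    "g_divide",
    "zadeh_divide",
    "metric_D",
    "validate",
    "membership",
    "extension_divide_oracle",
    "to_json",
    "from_json",
]

#: slack used when comparing endpoint arrays for monotonicity / ordering
_TIE_TOL = 1e-12


class MixedCaseError(ValueError):
    """The g-division case inequality changes sign across grid levels."""

    def __init__(self, message: str, levels: np.ndarray):
        super().__init__(message)
        self.levels = np.asarray(levels)


class ImproperResultError(ValueError):
    """An operation produced endpoint arrays that are not a fuzzy number."""


class CaseLabel(enum.Enum):
    """Which g-division branch applies (same-side vs. cross-assigned quotients)."""

    CASE_I = "case1"
    CASE_II = "case2"


@dataclass(frozen=True)
class AlphaGrid:
    """Ordered membership levels, always spanning 0 (support) to 1 (core)."""

    levels: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "levels", levels)
        if levels.ndim != 1 or levels.size < 2:
            raise ValueError("alpha grid needs at least the levels 0 and 1")
        if levels[0] != 0.0 or levels[-1] != 1.0:
            raise ValueError("alpha grid must start at 0 and end at 1")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("alpha levels must be strictly increasing")

    @classmethod
    def uniform(cls, n: int = 101) -> "AlphaGrid":
        """Uniform grid of ``n`` levels; the default 101 includes the quartiles."""
        return cls(np.linspace(0.0, 1.0, n))

    def __len__(self) -> int:
        return self.levels.size

    def __eq__(self, other) -> bool:
        return isinstance(other, AlphaGrid) and np.array_equal(self.levels, other.levels)

    def __hash__(self):
        return hash(self.levels.tobytes())

    def index_of(self, alpha: float) -> int:
        """Index of an exact grid level; raises if ``alpha`` is not on the grid."""
        idx = int(np.argmin(np.abs(self.levels - alpha)))
        if abs(self.levels[idx] - alpha) > 1e-12:
            raise KeyError(f"alpha={alpha} is not a grid level")
        return idx


@dataclass(frozen=True)
class ParabolicSpec:
    """Parabolic fuzzy number: membership 1 - ((x-c)/s)^2 on [c-s, c+s].

    Its alpha-cut is ``[c - s*sqrt(1-alpha), c + s*sqrt(1-alpha)]``; positivity
    of the support requires ``c > s``.
    """

    center: float
    spread: float

    def __post_init__(self):
        if self.spread < 0:
            raise ValueError("spread must be nonnegative")

    def cut(self, alpha) -> tuple[np.ndarray, np.ndarray]:
        """Exact alpha-cut endpoints at the given level(s)."""
        a = np.asarray(alpha, dtype=float)
        half = self.spread * np.sqrt(1.0 - a)
        return self.center - half, self.center + half


@dataclass(frozen=True)
class FuzzyNumber:
    """Alpha-cut family: left/right endpoints over a shared alpha grid."""

    grid: AlphaGrid
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "left", np.asarray(self.left, dtype=float))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=float))
        if self.left.shape != self.grid.levels.shape or self.right.shape != self.grid.levels.shape:
            raise ValueError("endpoint arrays must match the alpha grid")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.left[0]), float(self.right[0])

    @property
    def core(self) -> tuple[float, float]:
        return float(self.left[-1]), float(self.right[-1])

    @property
    def width(self) -> np.ndarray:
        """Per-level cut width ``right - left``."""
        return self.right - self.left

    @property
    def is_crisp(self) -> bool:
        return bool(np.all(np.abs(self.right - self.left) <= _TIE_TOL))

    @property
    def is_positive(self) -> bool:
        return bool(self.left[0] > 0)

    def cut(self, alpha: float) -> tuple[float, float]:
        """Alpha-cut at an exact grid level."""
        i = self.grid.index_of(alpha)
        return float(self.left[i]), float(self.right[i])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FuzzyNumber)
            and self.grid == other.grid
            and np.array_equal(self.left, other.left)
            and np.array_equal(self.right, other.right)
        )

    def __hash__(self):
        return hash((self.grid, self.left.tobytes(), self.right.tobytes()))

    def __repr__(self) -> str:
        lo, hi = self.support
        cl, cr = self.core
        core = f"{cl:.6g}" if abs(cr - cl) <= _TIE_TOL else f"[{cl:.6g}, {cr:.6g}]"
        return f"FuzzyNumber(supp=[{lo:.6g}, {hi:.6g}], core={core}, levels={len(self.grid)})"


@dataclass
class ValidationReport:
    valid: bool
    positive: bool
    issues: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.valid


def validate(F: FuzzyNumber, require_positive: bool = False) -> ValidationReport:
    """Check the nested-interval structure of an alpha-cut family.

    Valid means: left endpoints nondecreasing in alpha, right endpoints
    nonincreasing, ``left <= right`` at every level (so the cuts are nested),
    and all entries finite.
    """
    issues = []
    if not (np.all(np.isfinite(F.left)) and np.all(np.isfinite(F.right))):
        issues.append("non-finite endpoints")
    if np.any(np.diff(F.left) < -_TIE_TOL):
        issues.append("left endpoints not nondecreasing in alpha")
    if np.any(np.diff(F.right) > _TIE_TOL):
        issues.append("right endpoints not nonincreasing in alpha")
    if np.any(F.left > F.right + _TIE_TOL):
        issues.append("left endpoint exceeds right endpoint")
    positive = bool(F.left[0] > 0)
    if require_positive and not positive:
        issues.append("support is not strictly positive")
    return ValidationReport(valid=not issues, positive=positive, issues=issues)


def make_parabolic(
    center: float, spread: float, grid: AlphaGrid, require_positive: bool = True
) -> FuzzyNumber:
    """Parabolic fuzzy number with the given membership-1 point and half-width."""
    if spread <= 0:
        raise ValueError("spread must be positive; use make_crisp for point values")
    if require_positive and center - spread <= 0:
        raise ValueError(f"support [{center - spread}, {center + spread}] is not positive")
    left, right = ParabolicSpec(center, spread).cut(grid.levels)
    return FuzzyNumber(grid, left, right)


def make_crisp(value: float, grid: AlphaGrid) -> FuzzyNumber:
    """Trivial (zero-width) fuzzy number equal to ``value`` at every level."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    v = np.full(len(grid), float(value))
    return FuzzyNumber(grid, v, v.copy())


def _same_grid(H: FuzzyNumber, P: FuzzyNumber) -> None:
    if H.grid != P.grid:
        raise ValueError("operands live on different alpha grids")


def add(H: FuzzyNumber, P: FuzzyNumber) -> FuzzyNumber:
    """Levelwise interval addition."""
    _same_grid(H, P)
    return FuzzyNumber(H.grid, H.left + P.left, H.right + P.right)


def scale(k: float, H: FuzzyNumber) -> FuzzyNumber:
    """Multiply by a positive real."""
    if k <= 0:
        raise ValueError("scale factor must be positive")
    return FuzzyNumber(H.grid, k * H.left, k * H.right)


def multiply(H: FuzzyNumber, P: FuzzyNumber) -> FuzzyNumber:
    """Levelwise product of positive fuzzy numbers: [L_H L_P, R_H R_P]."""
    _same_grid(H, P)
    if not (H.is_positive and P.is_positive):
        raise ValueError("multiply requires positive operands")
    return FuzzyNumber(H.grid, H.left * P.left, H.right * P.right)


def _classify_sign(d: np.ndarray, levels: np.ndarray, what: str) -> CaseLabel:
    """Uniform-sign classification with ties compatible with either case.

    ``d <= 0`` everywhere selects Case I; otherwise ``d >= 0`` everywhere
    selects Case II.  A level with ``d == 0`` (always the crisp core when the
    operands' alpha=1 cuts are points) is compatible with both branches, so
    only a genuine sign change across levels is rejected.
    """
    if np.all(d <= _TIE_TOL):
        return CaseLabel.CASE_I
    if np.all(d >= -_TIE_TOL):
        return CaseLabel.CASE_II
    pos = levels[d > _TIE_TOL]
    neg = levels[d < -_TIE_TOL]
    raise MixedCaseError(
        f"{what}: case inequality changes sign across alpha levels "
        f"(>0 at {pos[:5]}..., <0 at {neg[:5]}...)",
        np.concatenate([pos, neg]),
    )


def g_divide(
    H: FuzzyNumber, P: FuzzyNumber, allow_mixed: bool = False
) -> tuple[FuzzyNumber, CaseLabel]:
    """Generalized division ``W = H / P`` of positive fuzzy numbers.

    Case I (``H_l P_r <= H_r P_l`` at every level): ``W = [H_l/P_l, H_r/P_r]``,
    satisfying ``H = P * W``.  Case II (reverse inequality): the quotients are
    cross-assigned, ``W = [H_r/P_r, H_l/P_l]``, satisfying ``P = H * W^{-1}``.

    The case must be uniform across levels; a sign change raises
    :class:`MixedCaseError` unless ``allow_mixed`` is set, in which case the
    branch is chosen per level and the (non-canonical) result may be improper.
    """
    _same_grid(H, P)
    if not (H.is_positive and P.is_positive):
        raise ValueError("g-division requires positive operands")
    d = H.left * P.right - H.right * P.left
    if allow_mixed:
        case1 = d <= _TIE_TOL
        left = np.where(case1, H.left / P.left, H.right / P.right)
        right = np.where(case1, H.right / P.right, H.left / P.left)
        label = CaseLabel.CASE_I if bool(np.all(case1)) else CaseLabel.CASE_II
        return FuzzyNumber(H.grid, left, right), label
    label = _classify_sign(d, H.grid.levels, "g-division")
    if label is CaseLabel.CASE_I:
        W = FuzzyNumber(H.grid, H.left / P.left, H.right / P.right)
    else:
        W = FuzzyNumber(H.grid, H.right / P.right, H.left / P.left)
    rep = validate(W)
    if not rep.valid:
        raise ImproperResultError(f"g-division result is not a fuzzy number: {rep.issues}")
    return W, label


def zadeh_divide(H: FuzzyNumber, P: FuzzyNumber) -> FuzzyNumber:
    """Extension-principle division: ``[H_l/P_r, H_r/P_l]`` per level."""
    _same_grid(H, P)
    if not (H.is_positive and P.is_positive):
        raise ValueError("division requires positive operands (0 not in the support)")
    return FuzzyNumber(H.grid, H.left / P.right, H.right / P.left)


def metric_D(H: FuzzyNumber, P: FuzzyNumber) -> float:
    """Sup over alpha of the larger endpoint discrepancy (grid approximation).

    Exact whenever the endpoint discrepancies attain their extrema on the grid;
    for parabolic families that happens at the support (alpha=0).
    """
    _same_grid(H, P)
    return float(
        np.max(np.maximum(np.abs(H.left - P.left), np.abs(H.right - P.right)))
    )


def membership(F: FuzzyNumber, x) -> np.ndarray:
    """Membership grade of point(s) ``x``, read off the alpha-cut family.

    Reconstructed from the stored cuts: 0 outside the support, 1 on the core,
    and linear interpolation in alpha along each endpoint branch in between
    (exact at the grid levels).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    levels = F.grid.levels
    # rising branch L(alpha) and falling branch R(alpha), each invertible
    mu_left = np.interp(x, F.left, levels, left=0.0, right=1.0)
    mu_right = np.interp(x, F.right[::-1], levels[::-1], left=1.0, right=0.0)
    return np.minimum(mu_left, mu_right)


def extension_divide_oracle(
    H: FuzzyNumber, P: FuzzyNumber, n_samples: int = 2000
) -> FuzzyNumber:
    """Brute-force sup-min division used as an independent test oracle.

    Samples ``n_samples`` points across each operand's support, forms all
    pairwise quotients with membership ``min(mu_H, mu_P)``, and reads each
    alpha-cut as the min/max quotient whose pair membership reaches that
    level.  Endpoints agree with :func:`zadeh_divide` up to O(1/n_samples)
    sampling error.
    """
    if not (H.is_positive and P.is_positive):
        raise ValueError("oracle requires positive operands")
    # include the core endpoints so membership-1 pairs are sampled exactly
    xs = np.append(np.linspace(*H.support, n_samples), H.core)
    ys = np.append(np.linspace(*P.support, n_samples), P.core)
    mu = np.minimum.outer(membership(H, xs), membership(P, ys)).ravel()
    q = np.divide.outer(xs, ys).ravel()
    order = np.argsort(mu)
    mu, q = mu[order], q[order]
    # suffix extrema: cut at level a is the min/max of q over {mu >= a}
    lo = np.minimum.accumulate(q[::-1])[::-1]
    hi = np.maximum.accumulate(q[::-1])[::-1]
    starts = np.searchsorted(mu, H.grid.levels - 1e-12, side="left")
    starts = np.minimum(starts, mu.size - 1)
    return FuzzyNumber(H.grid, lo[starts], hi[starts])


# ---------------------------------------------------------------------------
# JSON serialization

def to_json(F: FuzzyNumber | ParabolicSpec, family: str | None = None) -> dict:
    """Serializable dict for a fuzzy number or parabolic spec."""
    if isinstance(F, ParabolicSpec):
        return {"family": "parabolic", "center": F.center, "spread": F.spread}
    if F.is_crisp:
        return {"family": "crisp", "center": float(F.left[-1])}
    return {
        "family": "alphacut",
        "alphas": F.grid.levels.tolist(),
        "left": F.left.tolist(),
        "right": F.right.tolist(),
    }


def from_json(obj: dict | str, grid: AlphaGrid | None = None) -> FuzzyNumber:
    """Rebuild a fuzzy number from its JSON form (see :func:`to_json`)."""
    if isinstance(obj, str):
        obj = json.loads(obj)
    family = obj.get("family", "alphacut")
    if family == "parabolic":
        if grid is None:
            raise ValueError("a grid is required to materialize a parabolic spec")
        return make_parabolic(obj["center"], obj["spread"], grid)
    if family == "crisp":
        if grid is None:
            raise ValueError("a grid is required to materialize a crisp value")
        return make_crisp(obj["center"], grid)
    if family == "alphacut":
        g = AlphaGrid(np.asarray(obj["alphas"], dtype=float))
        return FuzzyNumber(g, np.asarray(obj["left"]), np.asarray(obj["right"]))
    raise ValueError(f"unknown fuzzy-number family {family!r}")
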