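"""Alpha-cut arithmetic: construction, the two divisions, metric, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbqp import (
    AlphaGrid,
    CaseLabel,
    FuzzyNumber,
    MixedCaseError,
    add,
    extension_divide_oracle,
    from_json,
    g_divide,
    make_crisp,
    make_parabolic,
    membership,
    metric_D,
    multiply,
    scale,
    to_json,
    validate,
    zadeh_divide,
)


def const_interval(lo, hi, grid):
    """Fuzzy number whose every alpha-cut is [lo, hi] (rectangular membership)."""
    n = len(grid)
    return FuzzyNumber(grid, np.full(n, float(lo)), np.full(n, float(hi)))


# --- construction -----------------------------------------------------------


class TestMakeParabolic:
    def test_support_and_core(self, grid):
        A = make_parabolic(1.75, 0.25, grid)
        assert A.support == (1.5, 2.0)
        assert A.core == (1.75, 1.75)

    def test_quartile_cut(self, grid):
        # right endpoint at alpha=0.25 is 1.75 + 0.25*sqrt(0.75)
        A = make_parabolic(1.75, 0.25, grid)
        assert A.cut(0.25)[1] == pytest.approx(1.9665, abs=5e-5)

    def test_validates(self, grid):
        assert validate(make_parabolic(1.75, 0.25, grid)).valid

    def test_rejects_bad_spreads(self, grid):
        with pytest.raises(ValueError):
            make_parabolic(1.0, 0.0, grid)
        with pytest.raises(ValueError):
            make_parabolic(0.2, 0.25, grid)  # nonpositive support

    def test_crisp_is_zero_spread_limit(self, grid):
        c = make_crisp(1.75, grid)
        tiny = make_parabolic(1.75, 1e-9, grid)
        assert metric_D(c, tiny) < 1e-8


def test_make_crisp_zero_allowed_but_flagged(grid):
    z = make_crisp(0.0, grid)
    rep = validate(z, require_positive=True)
    assert rep.valid is False and not rep.positive
    assert validate(z).valid


# --- arithmetic -------------------------------------------------------------


def test_add_is_levelwise_interval_sum(grid):
    s = add(make_parabolic(1.75, 0.25, grid), make_parabolic(0.25, 0.1, grid))
    assert s.support == pytest.approx((1.65, 2.35))
    assert s.core == pytest.approx((2.0, 2.0))


def test_add_identity_and_grid_mismatch(grid, coarse_grid):
    H = make_parabolic(2.0, 0.5, grid)
    assert metric_D(add(H, make_crisp(0.0, grid)), H) == 0.0
    with pytest.raises(ValueError):
        add(H, make_crisp(0.0, coarse_grid))


def test_scale(grid):
    H = make_parabolic(2.0, 1.0, grid)
    assert scale(0.5, H).support == pytest.approx((0.5, 1.5))
    assert metric_D(scale(1.0, H), H) == 0.0
    with pytest.raises(ValueError):
        scale(-1.0, H)


def test_multiply_positive_supports(grid):
    # product of the two older initial-value supports: [0.65,1.35]*[0.75,1.25]
    P = multiply(make_parabolic(1.0, 0.35, grid), make_parabolic(1.0, 0.25, grid))
    assert P.support == pytest.approx((0.4875, 1.6875))


# --- g-division -------------------------------------------------------------


class TestGDivision:
    def test_case1_roundtrip_identity(self, grid):
        H, P = const_interval(2, 4, grid), const_interval(1, 2, grid)
        W, label = g_divide(H, P)
        assert label is CaseLabel.CASE_I
        assert np.allclose(W.left, 2) and np.allclose(W.right, 2)
        assert metric_D(multiply(P, W), H) < 1e-12

    def test_case2_cross_assignment_identity(self, grid):
        H, P = const_interval(2, 3, grid), const_interval(1, 4, grid)
        W, label = g_divide(H, P)
        assert label is CaseLabel.CASE_II
        assert np.allclose(W.left, 0.75) and np.allclose(W.right, 2.0)
        # defining identity of the second branch: P = H * W^{-1}
        Winv = FuzzyNumber(grid, 1 / W.right, 1 / W.left)
        assert metric_D(multiply(H, Winv), P) < 1e-12

    def test_crisp_quotient(self, grid):
        W, label = g_divide(make_crisp(6.0, grid), make_crisp(2.0, grid))
        assert label is CaseLabel.CASE_I
        assert np.allclose(W.left, 3.0) and np.allclose(W.right, 3.0)

    def test_mixed_case_rejected_with_levels(self, grid):
        # relative width of P crosses that of H as alpha rises, so the case
        # inequality flips sign between the support and the core
        H = const_interval(1, 2, grid)
        P = FuzzyNumber(grid, np.ones(len(grid)), 3.0 - 1.5 * grid.levels)
        assert validate(P).valid
        with pytest.raises(MixedCaseError) as err:
            g_divide(H, P)
        assert len(err.value.levels) > 0

    def test_allow_mixed_flag_returns_per_level(self, grid):
        H, P = const_interval(2, 3, grid), const_interval(1, 4, grid)
        W, _ = g_divide(H, P, allow_mixed=True)
        assert np.allclose(W.left, 0.75)


def test_zadeh_division_interval_quotient(grid):
    H, P = const_interval(2, 3, grid), const_interval(1, 4, grid)
    W = zadeh_divide(H, P)
    assert np.allclose(W.left, 0.5) and np.allclose(W.right, 3.0)
    crisp = zadeh_divide(make_crisp(6.0, grid), make_crisp(2.0, grid))
    assert np.allclose(crisp.left, 3.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    hc=st.floats(0.5, 5), hs=st.floats(0.01, 0.4),
    pc=st.floats(0.5, 5), ps=st.floats(0.01, 0.4),
)
def test_width_dominance_and_roundtrip(hc, hs, pc, ps):
    """Zadeh division is never narrower than g-division, and the g-quotient
    satisfies its defining multiplicative identity."""
    grid = AlphaGrid.uniform(21)
    H = make_parabolic(hc + hs, min(hs, 0.9 * hc), grid, require_positive=False)
    P = make_parabolic(pc + ps, min(ps, 0.9 * pc), grid, require_positive=False)
    Wz = zadeh_divide(H, P)
    try:
        Wg, label = g_divide(H, P)
    except MixedCaseError:
        return
    assert np.all(Wz.width >= Wg.width - 1e-12)
    if label is CaseLabel.CASE_I:
        back = multiply(P, Wg)
        assert np.max(np.abs(back.left - H.left) / np.abs(H.left)) < 1e-12
        assert np.max(np.abs(back.right - H.right) / np.abs(H.right)) < 1e-12
    else:
        Winv = FuzzyNumber(grid, 1 / Wg.right, 1 / Wg.left)
        back = multiply(H, Winv)
        assert np.max(np.abs(back.left - P.left) / np.abs(P.left)) < 1e-12
        assert np.max(np.abs(back.right - P.right) / np.abs(P.right)) < 1e-12


# --- metric -----------------------------------------------------------------


def test_metric_properties(grid):
    H = make_parabolic(1.75, 0.25, grid)
    assert metric_D(H, H) == 0.0
    assert metric_D(const_interval(1, 2, grid), const_interval(1.5, 2.5, grid)) == 0.5
    # max discrepancy against the crisp center sits at the support
    assert metric_D(H, make_crisp(1.75, grid)) == pytest.approx(0.25)


# --- membership and the extension-principle oracle --------------------------


def test_membership_matches_parabola(grid):
    H = make_parabolic(1.0, 0.5, grid)
    xs = np.array([0.4, 0.5, 1.0, 1.3, 1.6])
    expected = np.clip(1 - ((xs - 1.0) / 0.5) ** 2, 0, 1)
    got = membership(H, xs)
    # step-function approximation on 101 levels: within one grid step
    assert np.all(np.abs(got - expected) <= 0.0101)
    assert got[0] == 0.0 and got[-1] == 0.0


class TestExtensionOracle:
    def test_crisp_quotient_exact(self, coarse_grid):
        W = extension_divide_oracle(
            make_crisp(6.0, coarse_grid), make_crisp(2.0, coarse_grid), 100
        )
        assert np.allclose(W.left, 3.0) and np.allclose(W.right, 3.0)

    def test_rectangular_operands(self, coarse_grid):
        H = const_interval(2, 3, coarse_grid)
        P = const_interval(1, 4, coarse_grid)
        W = extension_divide_oracle(H, P, 2000)
        assert np.all(np.abs(W.left - 0.5) < 5e-3)
        assert np.all(np.abs(W.right - 3.0) < 5e-3)

    def test_agrees_with_zadeh_on_random_pairs(self, coarse_grid, rng):
        """Sup-min sampling reproduces the levelwise interval quotient on >= 50
        random positive parabolic pairs."""
        for _ in range(50):
            hc, pc = rng.uniform(0.5, 4, 2)
            hs = rng.uniform(0.05, 0.8) * hc * 0.9
            ps = rng.uniform(0.05, 0.8) * pc * 0.9
            H = make_parabolic(hc, hs, coarse_grid)
            P = make_parabolic(pc, ps, coarse_grid)
            W = zadeh_divide(H, P)
            O = extension_divide_oracle(H, P, 800)
            # first-order sampling error of x/y: (dx + q dy)/y with
            # dx, dy one sample spacing and y bounded below by the support
            tol = (
                3.0
                * (H.width[0] + float(W.right[0]) * P.width[0])
                / (800 * P.support[0])
            )
            assert np.max(np.abs(O.left - W.left)) < max(tol, 5e-3)
            assert np.max(np.abs(O.right - W.right)) < max(tol, 5e-3)


# --- nestedness property ----------------------------------------------------


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    c1=st.floats(0.5, 3), s1=st.floats(0.01, 0.3),
    c2=st.floats(0.5, 3), s2=st.floats(0.01, 0.3),
    k=st.floats(0.1, 5),
)
def test_ops_preserve_nestedness(c1, s1, c2, s2, k):
    grid = AlphaGrid.uniform(21)
    H = make_parabolic(c1 + s1, min(s1, 0.9 * c1), grid)
    P = make_parabolic(c2 + s2, min(s2, 0.9 * c2), grid)
    for out in (add(H, P), scale(k, H), multiply(H, P), zadeh_divide(H, P)):
        assert validate(out).valid


def test_crisp_degeneration_equals_real_arithmetic(grid):
    a, b = make_crisp(6.0, grid), make_crisp(1.5, grid)
    assert np.allclose(add(a, b).left, 7.5)
    assert np.allclose(multiply(a, b).left, 9.0)
    assert np.allclose(zadeh_divide(a, b).left, 4.0)
    W, _ = g_divide(a, b)
    assert np.allclose(W.left, 4.0) and np.allclose(W.right, 4.0)


# --- serialization ----------------------------------------------------------


def test_json_roundtrip(grid):
    H = make_parabolic(1.75, 0.25, grid)
    back = from_json(to_json(H))
    assert metric_D(H, back) == 0.0
    crisp = from_json(to_json(make_crisp(2.0, grid)), grid)
    assert crisp.is_crisp and crisp.core == (2.0, 2.0)
    par = from_json({"family": "parabolic", "center": 1.75, "spread": 0.25}, grid)
    assert metric_D(H, par) == 0.0
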