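"""Desirability transform shapes, boundaries, and invariants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from desirank import (
    DesirabilityFunctionSpec,
    DegenerateVariableError,
    InvalidSpecError,
    d_extreme,
    d_high,
    d_low,
    d_target,
    resolve_percentile_cuts,
    transform_variable,
)
from conftest import scalar_d_extreme, scalar_d_high, scalar_d_low, scalar_d_target


# ---------------------------------------------------------------- examples


@pytest.mark.parametrize(
    "y, expected",
    [
        (0.0001, 1.0),       # boundary Y = A sits on the closed saturated branch
        (0.1, 0.0),          # boundary Y = B
        (0.05, (0.05 - 0.1) / (0.0001 - 0.1)),
        (0.0, 1.0),          # an exact-zero P-value is simply below A
        (0.2, 0.0),
    ],
)
def test_d_low_pvalue_cuts(y, expected):
    assert d_low(y, 0.0001, 0.1, 1) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "y, s, expected",
    [(2, 1, 0.5), (2, 2, 0.25), (5, 7, 1.0), (0.5, 1, 0.0), (1, 1, 0.0), (3, 1, 1.0)],
)
def test_d_high_midpoint_and_saturation(y, s, expected):
    assert d_high(y, 1, 3, s) == pytest.approx(expected)


@pytest.mark.parametrize(
    "y, expected",
    [
        (-2.0, 1.0),   # saturated tail
        (-1.5, 1.0),   # outer cut belongs to the tail
        (0.0, 0.0),    # middle plateau
        (0.5, 0.0),
        (1.0, 0.5),    # halfway up the right flank
        (-1.0, 0.5),
        (2.0, 1.0),
    ],
)
def test_d_extreme_fold_change_valley(y, expected):
    assert d_extreme(y, -1.5, -0.5, 0.5, 1.5, 1) == pytest.approx(expected)


@pytest.mark.parametrize(
    "y, expected", [(1.0, 1.0), (0.5, 0.5), (3.0, 0.0), (-1.0, 0.0), (1.5, 0.5)]
)
def test_d_target_peak(y, expected):
    assert d_target(y, 0, 1, 2, 1) == pytest.approx(expected)


def test_invalid_cut_order_rejected():
    with pytest.raises(InvalidSpecError):
        d_low(0.5, 1.0, 1.0, 1)
    with pytest.raises(InvalidSpecError):
        d_high(0.5, 2.0, 1.0, 1)
    with pytest.raises(InvalidSpecError):
        d_extreme(0.0, -1.0, -2.0, 1.0, 2.0, 1)
    with pytest.raises(InvalidSpecError):
        d_target(0.5, 0.0, 2.0, 1.0, 1)
    with pytest.raises(InvalidSpecError):
        d_low(0.5, 0.0, 1.0, 0.0)
    with pytest.raises(InvalidSpecError):
        DesirabilityFunctionSpec(kind="low", cuts=(1.0, 1.0))


def test_missing_values_propagate():
    out = d_low(np.array([0.05, np.nan, np.inf]), 0.0001, 0.1)
    assert np.isfinite(out[0])
    assert np.isnan(out[1]) and np.isnan(out[2])
    assert math.isnan(d_high(float("nan"), 0, 1))


# ------------------------------------------------------------- percentiles


def test_percentile_cuts_match_empirical_quantiles():
    values = np.arange(1.0, 101.0)  # 1..100 equally spaced
    spec = DesirabilityFunctionSpec(kind="low", cuts=(5, 95), cut_mode="percentile")
    resolved = resolve_percentile_cuts(spec, values)
    assert resolved.cut_mode == "numeric"
    assert resolved.cuts == pytest.approx(
        (np.percentile(values, 5), np.percentile(values, 95))
    )
    assert resolved.cuts[0] < resolved.cuts[1]


def test_extreme_percentile_cuts_expand_middle_band():
    rng = np.random.default_rng(0)
    values = rng.normal(0, 1, 2001)
    spec = DesirabilityFunctionSpec(
        kind="extreme", cuts=(5, 50, 95), cut_mode="percentile"
    )
    resolved = resolve_percentile_cuts(spec, values)
    assert resolved.cuts == pytest.approx(
        tuple(np.percentile(values, [5, 25, 75, 95]))
    )
    # the middle 50% of observations maps to the zero plateau
    d = transform_variable(values, spec)
    q25, q75 = np.percentile(values, [25, 75])
    inner = (values >= q25) & (values <= q75)
    assert np.all(d[inner] == 0.0)
    outer = (values <= np.percentile(values, 5)) | (values >= np.percentile(values, 95))
    assert np.all(d[outer] == 1.0)


def test_extreme_percentile_zero_to_hundred_spans_range():
    values = np.linspace(-3, 3, 101)
    spec = DesirabilityFunctionSpec(kind="low", cuts=(0, 100), cut_mode="percentile")
    resolved = resolve_percentile_cuts(spec, values)
    assert resolved.cuts == pytest.approx((values.min(), values.max()))


def test_degenerate_variable_rejected():
    spec = DesirabilityFunctionSpec(kind="low", cuts=(5, 95), cut_mode="percentile")
    with pytest.raises(DegenerateVariableError):
        resolve_percentile_cuts(spec, np.array([1.0, 1.0, np.nan]))


def test_top_five_percent_of_pvalues_is_smallest_tail():
    """For a small-is-desirable variable, the 5% saturation sits at the
    smallest values: everything at or below the 5th quantile scores 1."""
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 500)
    spec = DesirabilityFunctionSpec(kind="low", cuts=(5, 95), cut_mode="percentile")
    d = transform_variable(p, spec)
    q5 = np.percentile(p, 5)
    assert np.all(d[p <= q5] == 1.0)
    assert np.all(d[p >= np.percentile(p, 95)] == 0.0)


# ---------------------------------------------------------- transform API


def test_transform_variable_preserves_missing_and_rescales():
    spec = DesirabilityFunctionSpec(kind="low", cuts=(0.0001, 0.1))
    y = np.array([0.0001, 0.05, 0.1, np.nan])
    d = transform_variable(y, spec)
    assert d[:3] == pytest.approx([1.0, 0.50050050050, 0.0], abs=1e-9)
    assert np.isnan(d[3])

    bounded = dataclasses.replace(spec, d_min=0.2, d_max=1.0)
    db = transform_variable(y, bounded)
    assert db[0] == pytest.approx(1.0)
    assert db[2] == pytest.approx(0.2)
    assert np.nanmin(db) >= 0.2 and np.nanmax(db) <= 1.0


def test_all_below_a_high_spec_gives_floor():
    spec = DesirabilityFunctionSpec(kind="high", cuts=(10.0, 20.0))
    assert np.all(transform_variable(np.array([1.0, 2.0, 9.9]), spec) == 0.0)


# --------------------------------------------------------------- properties

finite = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)
scales = st.floats(min_value=0.05, max_value=8.0)


@st.composite
def low_high_params(draw):
    a = draw(finite)
    b = a + draw(st.floats(min_value=1e-3, max_value=1e6))
    return a, b, draw(scales)


@settings(max_examples=300, derandomize=True)
@given(y=finite, params=low_high_params())
def test_range_and_duality(y, params):
    a, b, s = params
    dl = d_low(y, a, b, s)
    dh = d_high(y, a, b, s)
    assert 0.0 <= dl <= 1.0
    assert 0.0 <= dh <= 1.0
    # mirror symmetry: shrinking Y under d_low is growing -Y under d_high
    assert d_high(-y, -b, -a, s) == pytest.approx(dl, abs=1e-9)


@settings(max_examples=300, derandomize=True)
@given(y1=finite, y2=finite, params=low_high_params())
def test_monotonicity(y1, y2, params):
    a, b, s = params
    lo, hi = min(y1, y2), max(y1, y2)
    assert d_low(lo, a, b, s) >= d_low(hi, a, b, s)
    assert d_high(lo, a, b, s) <= d_high(hi, a, b, s)


@settings(max_examples=200, derandomize=True)
@given(params=low_high_params(), t=st.floats(min_value=1e-3, max_value=1 - 1e-3))
def test_linear_scale_is_straight_line_interior(params, t):
    a, b, _ = params
    y = a + t * (b - a)
    assert d_low(y, a, b, 1.0) == pytest.approx(1.0 - t, rel=1e-4, abs=1e-5)
    assert d_high(y, a, b, 1.0) == pytest.approx(t, rel=1e-4, abs=1e-5)
    assert 0.0 < d_high(y, a, b, 1.0) < 1.0


def test_extreme_symmetry():
    cuts = (-1.5, -0.5, 0.5, 1.5)
    ys = np.linspace(0, 3, 301)
    np.testing.assert_allclose(
        d_extreme(ys, *cuts, 2.0), d_extreme(-ys, *cuts, 2.0), atol=1e-12
    )


def test_vectorized_matches_scalar_reference_bulk():
    """Vectorised transforms agree with pointwise evaluation of the piecewise
    formulas on a large random grid (all four kinds)."""
    rng = np.random.default_rng(42)
    n = 4000
    for _ in range(3):
        a, spread1, spread2, spread3 = rng.uniform(0.1, 5.0, 4)
        a0 = rng.uniform(-10, 10)
        s = rng.uniform(0.2, 4.0)
        y = rng.uniform(a0 - 10, a0 + 20, n)
        y[rng.random(n) < 0.02] = np.nan
        np.testing.assert_allclose(
            d_low(y, a0, a0 + spread1, s),
            [scalar_d_low(v, a0, a0 + spread1, s) for v in y],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            d_high(y, a0, a0 + spread1, s),
            [scalar_d_high(v, a0, a0 + spread1, s) for v in y],
            atol=1e-12,
        )
        cuts = (a0, a0 + spread1, a0 + spread1 + spread2,
                a0 + spread1 + spread2 + spread3)
        np.testing.assert_allclose(
            d_extreme(y, *cuts, s),
            [scalar_d_extreme(v, *cuts, s) for v in y],
            atol=1e-12,
        )
        tcuts = (a0, a0 + spread1, a0 + spread1 + spread2)
        np.testing.assert_allclose(
            d_target(y, *tcuts, s),
            [scalar_d_target(v, *tcuts, s) for v in y],
            atol=1e-12,
        )


def test_percentile_numeric_equivalence():
    """Transforming with percentile cuts equals transforming with the
    pre-computed numeric quantiles of the same data."""
    rng = np.random.default_rng(7)
    for kind, cuts in [("low", (10, 90)), ("high", (10, 90)),
                       ("extreme", (5, 50, 95)), ("target", (10, 50, 90))]:
        values = rng.normal(0, 2, 500)
        pspec = DesirabilityFunctionSpec(kind=kind, cuts=cuts, cut_mode="percentile")
        nspec = resolve_percentile_cuts(pspec, values)
        np.testing.assert_allclose(
            transform_variable(values, pspec),
            transform_variable(values, nspec),
            atol=1e-12,
        )
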