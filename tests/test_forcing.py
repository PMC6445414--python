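"""Forcing construction: sea-ice index, gap filling, seasonal expansion,
response curves."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wapfoodweb import (
    AnnualIndex,
    MonthlyTimeSeries,
    ResponseCurve,
    build_sea_ice_index,
    evaluate_response_curve,
    expand_annual_series,
    gap_fill_monthly,
)
from wapfoodweb.forcing import ForcingError


def monthly(values, start="2000-01"):
    idx = pd.period_range(start, periods=len(values), freq="M")
    return MonthlyTimeSeries(pd.Series(values, index=idx))


# -- sea-ice index ----------------------------------------------------------


def test_constant_series_gives_unit_index():
    idx = build_sea_ice_index(monthly([5.0] * 36))
    assert np.allclose(idx.values, 1.0)


def test_two_year_toy_minima():
    vals = [100.0] * 12 + [300.0] * 12
    idx = build_sea_ice_index(monthly(vals))
    assert idx[2000] == pytest.approx(0.5)
    assert idx[2001] == pytest.approx(1.5)


def test_declining_minima_give_declining_indices():
    vals = []
    for y in range(5):
        base = 100.0 * (1 - 0.1 * y)
        vals += [base + 50 * m for m in range(12)]  # min is the January value
    idx = build_sea_ice_index(monthly(vals))
    diffs = np.diff(idx.values.to_numpy())
    assert (diffs < 0).all()


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=24, max_size=60).filter(
        lambda v: len(v) % 12 == 0
    )
)
def test_index_mean_is_one_for_any_series(values):
    idx = build_sea_ice_index(monthly(values))
    assert idx.values.mean() == pytest.approx(1.0, abs=1e-9)


def test_partial_year_rejected_unless_allowed():
    with pytest.raises(ForcingError, match="months"):
        build_sea_ice_index(monthly([1.0] * 15))
    idx = build_sea_ice_index(monthly([1.0] * 15), allow_partial=True)
    assert set(idx.years) == {2000, 2001}


def test_monthly_expansion_repeats_annual_value():
    idx = AnnualIndex(pd.Series({2000: 0.5, 2001: 1.5}))
    ts = idx.to_monthly()
    assert len(ts) == 24
    assert (ts.values[:12] == 0.5).all() and (ts.values[12:] == 1.5).all()


# -- gap filling ------------------------------------------------------------


def test_gap_fill_identity_without_gaps():
    s = monthly(np.arange(24.0))
    out = gap_fill_monthly(s)
    assert (out.values == s.values).all()


def test_gap_fill_uses_calendar_month_mean():
    vals = list(range(1, 13)) + [float("nan")] * 12 + list(range(13, 25))
    vals[18] = float("nan")  # July of year 2
    s = monthly(vals)
    out = gap_fill_monthly(s)
    # July observations are 7 and 19 -> climatology 13
    assert out.values.iloc[18] == pytest.approx(13.0)


def test_gap_fill_matches_brute_force_on_random_mask():
    rng = np.random.default_rng(3)
    vals = rng.uniform(1, 10, 120)
    mask = rng.random(120) < 0.2
    masked = np.where(mask, np.nan, vals)
    # keep at least one observation per calendar month
    for m in range(12):
        masked[m] = vals[m]
    out = gap_fill_monthly(monthly(masked))
    for k in range(120):
        if math.isnan(masked[k]):
            same_month = [masked[j] for j in range(120) if j % 12 == k % 12 and not math.isnan(masked[j])]
            assert out.values.iloc[k] == pytest.approx(float(np.mean(same_month)))
        else:
            assert out.values.iloc[k] == masked[k]


def test_gap_fill_idempotent():
    rng = np.random.default_rng(5)
    vals = np.where(rng.random(48) < 0.2, np.nan, rng.uniform(0, 4, 48))
    vals[:12] = 1.0
    once = gap_fill_monthly(monthly(vals))
    twice = gap_fill_monthly(once)
    assert (once.values == twice.values).all()


def test_gap_fill_rejects_month_with_no_observations():
    vals = [np.nan if k % 12 == 3 else 1.0 for k in range(24)]
    with pytest.raises(ForcingError, match="no observations"):
        gap_fill_monthly(monthly(vals))


# -- seasonal expansion -----------------------------------------------------

OCT_MAY = {10, 11, 12, 1, 2, 3, 4, 5}


def test_breeding_season_expansion():
    annual = AnnualIndex(pd.Series({2003: 0.1, 2004: 0.2}))
    ts = expand_annual_series(annual, OCT_MAY, zero_before="2003-10")
    v = ts.values
    assert (v[pd.period_range("2003-10", "2004-05", freq="M")] == 0.1).all()
    assert (v[pd.period_range("2004-06", "2004-09", freq="M")] == 0.0).all()
    assert (v[pd.period_range("2004-10", "2005-05", freq="M")] == 0.2).all()
    assert (v[: pd.Period("2003-09", "M")] == 0.0).all()


def test_zero_before_end_blanks_everything():
    annual = AnnualIndex(pd.Series({2000: 1.0}))
    ts = expand_annual_series(annual, OCT_MAY, zero_before="2002-01")
    assert (ts.values == 0.0).all()


def test_all_months_active_is_plain_repetition():
    annual = AnnualIndex(pd.Series({2000: 0.3}))
    ts = expand_annual_series(annual, set(range(1, 13)))
    assert ts.values[pd.period_range("2000-01", "2000-12", freq="M")].sum() == pytest.approx(3.6)


def test_malformed_month_set_rejected():
    annual = AnnualIndex(pd.Series({2000: 1.0}))
    with pytest.raises(ForcingError):
        expand_annual_series(annual, {0, 13})


# -- response curves --------------------------------------------------------


@pytest.mark.parametrize(
    "curve",
    [
        ResponseCurve("linear", {"start": 0.0, "end": 60.0}),
        ResponseCurve("sigmoid", {"y_zero": 0.0, "y_base": 1.5, "y_end": 5.0, "steep": 3.0}),
        ResponseCurve(
            "normal",
            {"sd_left": 12, "data_width": 560, "sd_right": 100, "mean": 24, "max": 1},
        ),
    ],
    ids=["linear", "sigmoid", "normal"],
)
def test_curves_are_one_at_baseline(curve):
    assert evaluate_response_curve(curve, curve.baseline_x) == pytest.approx(1.0)


def test_linear_curve_through_origin_doubles():
    c = ResponseCurve("linear", {"start": 0.0, "end": 60.0}, domain=(0.0, 2.0), baseline_x=1.0)
    assert c.evaluate(0.0) == pytest.approx(0.0)
    assert c.evaluate(2.0) == pytest.approx(2.0)


def test_sigmoid_passes_through_its_anchors():
    c = ResponseCurve(
        "sigmoid", {"y_zero": 0.0, "y_base": 1.5, "y_end": 5.0, "steep": 3.0},
        domain=(0.0, 3.0),
    )
    assert c._raw(np.array([1.0]))[0] == pytest.approx(1.5, abs=1e-12)
    # the raw curve approaches y_end far right of the inflection
    assert c._raw(np.array([30.0]))[0] == pytest.approx(5.0, rel=1e-3)
    # normalised outputs are monotone for a monotone raw shape
    xs = np.linspace(0, 3, 50)
    ys = c.evaluate(xs)
    assert (np.diff(ys) >= 0).all() and (ys >= 0).all()


def test_normal_curve_decreasing_right_of_mode():
    c = ResponseCurve(
        "normal",
        {"sd_left": 12, "data_width": 560, "sd_right": 100, "mean": 24, "max": 1},
        domain=(0.0, 2.0),
    )
    xs = np.linspace(0.2, 2.0, 30)
    assert (np.diff(c.evaluate(xs)) < 0).all()


def test_inputs_clamped_to_domain():
    c = ResponseCurve("linear", {"start": 0.0, "end": 10.0}, domain=(0.0, 2.0))
    assert c.evaluate(5.0) == c.evaluate(2.0)


def test_degenerate_domain_rejected():
    with pytest.raises(ForcingError, match="degenerate"):
        ResponseCurve("linear", {"start": 0, "end": 1}, domain=(1.0, 1.0))
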