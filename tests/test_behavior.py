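"""Behavioral metrics: outcomes, d', learning phases, licking, pupil."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popact import behavior as bh


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ttype,licked,expected", [
    ("Go", True, "Hit"),
    ("Go", False, "Miss"),
    ("Nogo", True, "FA"),
    ("Nogo", False, "CR"),
    ("catch", True, "catch-FA"),
    ("catch", False, "catch-CR"),
])
def test_classify_outcome(ttype, licked, expected):
    assert bh.classify_outcome(ttype, licked) == expected


def test_classify_outcome_unknown_type():
    with pytest.raises(ValueError):
        bh.classify_outcome("Maybe", True)


def test_grace_period_touch_is_not_a_response():
    # a touch 0.1 s after window onset is ignored; 0.8 s counts
    assert not bh.licked_in_response_window([10.1], 10.0, 1.5)
    assert bh.licked_in_response_window([10.8], 10.0, 1.5)
    # a Go trial with only the accidental touch is a Miss
    licked = bh.licked_in_response_window([10.1], 10.0, 1.5)
    assert bh.classify_outcome("Go", licked) == "Miss"


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------

def _inverse_normal_oracle(p: float, tol: float = 1e-13) -> float:
    """Standard-normal inverse CDF by bisection on math.erfc (scipy-free)."""
    lo, hi = -40.0, 40.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if 0.5 * math.erfc(-mid / math.sqrt(2)) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def test_d_prime_zero_when_ratios_equal():
    assert bh.d_prime(5, 5, 5, 5) == pytest.approx(0.0, abs=1e-12)


def test_d_prime_matches_inverse_normal_oracle():
    got = bh.d_prime(38, 4, 10, 88)
    expected = _inverse_normal_oracle(38 / 42) - _inverse_normal_oracle(10 / 98)
    assert got == pytest.approx(expected, abs=1e-9)


def test_d_prime_ratio_adjustment_at_one():
    # 42/0 hits: ratio adjusted to 1 - 1/(2*42) before the inverse CDF
    got = bh.d_prime(42, 0, 10, 88)
    expected = _inverse_normal_oracle(1 - 1 / 84) - _inverse_normal_oracle(10 / 98)
    assert math.isfinite(got)
    assert got == pytest.approx(expected, abs=1e-9)


def test_d_prime_zero_ratio_adjustment():
    got = bh.d_prime(42, 0, 0, 98)
    expected = _inverse_normal_oracle(1 - 1 / 84) - _inverse_normal_oracle(1 / 196)
    assert got == pytest.approx(expected, abs=1e-9)


def test_d_prime_requires_both_classes():
    with pytest.raises(ValueError):
        bh.d_prime(0, 0, 5, 5)


@given(st.integers(1, 60), st.integers(0, 60), st.integers(1, 60), st.integers(0, 60))
@settings(deadline=None, max_examples=50)
def test_d_prime_antisymmetric_under_swap(h, m, f, c):
    assert bh.d_prime(h, m, f, c) == pytest.approx(-bh.d_prime(f, c, h, m), abs=1e-10)


# ---------------------------------------------------------------------------
# learning phases
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("series,onset", [
    ([0.2, 0.9, 1.6, 1.7, 1.8], 4),
    ([1.6, 1.7, 1.2, 1.6, 1.7, 1.8], 5),
    ([0.1, 0.2, 0.3, 0.4], None),
])
def test_learning_phase_onset(series, onset):
    naive, expert, got = bh.learning_phases(series)
    assert got == onset
    if onset is None:
        assert expert == [] or all(series[i] > 1.5 for i in expert)


def test_no_expert_sessions_below_threshold():
    naive, expert, onset = bh.learning_phases([0.2, 0.4, 1.0, 1.2])
    assert expert == []
    assert onset is None
    assert naive == [0, 1, 2]


def _scan_oracle(d, thr=1.5, run=3):
    count = 0
    for i, v in enumerate(d):
        count = count + 1 if v > thr else 0
        if count >= run:
            return i
    return None


@given(st.lists(st.floats(0, 3, allow_nan=False), min_size=3, max_size=25))
@settings(deadline=None, max_examples=100)
def test_learning_phases_agree_with_scan_oracle(series):
    _, expert, onset = bh.learning_phases(series)
    assert onset == _scan_oracle(series)
    assert expert == [i for i, v in enumerate(series) if v > 1.5]


# ---------------------------------------------------------------------------
# anticipatory licking
# ---------------------------------------------------------------------------

def test_response_window_licks_not_counted_in_delay():
    windows = [(2.0, 4.0), (10.0, 12.0)]
    counts, _ = bh.anticipatory_licks([4.5, 12.3], windows)
    assert counts.tolist() == [0, 0]


def test_lick_at_delay_end_excluded_half_open():
    counts, _ = bh.anticipatory_licks([4.0], [(2.0, 4.0)])
    assert counts.tolist() == [0]
    counts, _ = bh.anticipatory_licks([2.0], [(2.0, 4.0)])
    assert counts.tolist() == [1]


def test_poisson_rate_recovered():
    rng = np.random.default_rng(3)
    rate, dur, n_trials = 1.5, 2.0, 300
    windows = [(10.0 * t, 10.0 * t + dur) for t in range(1, n_trials + 1)]
    licks = np.concatenate([
        lo + rng.uniform(0, dur, rng.poisson(rate * dur)) for lo, _ in windows
    ])
    counts, _ = bh.anticipatory_licks(licks, windows)
    se = np.sqrt(rate * dur / n_trials)
    assert abs(counts.mean() - rate * dur) < 3 * se


# ---------------------------------------------------------------------------
# pupil geometry
# ---------------------------------------------------------------------------

def test_circle_fit_exact_points():
    theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pts = np.column_stack([1 + 2 * np.cos(theta), -3 + 2 * np.sin(theta)])
    cx, cy, r = bh.fit_circle(pts)
    assert (cx, cy, r) == pytest.approx((1.0, -3.0, 2.0), abs=1e-9)


def test_pupil_area_radius_two_circle():
    theta = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    frame = np.column_stack([2 * np.cos(theta), 2 * np.sin(theta)])
    pts = np.tile(frame, (30, 1, 1))
    area = bh.pupil_area(pts)
    assert np.allclose(area, 4 * np.pi, atol=1e-8)


def test_pupil_missing_below_three_points():
    pts = np.full((5, 8, 2), np.nan)
    pts[:, :2, :] = 0.0  # only two visible points
    area = bh.pupil_area(pts)
    assert np.isnan(area).all()


def test_hampel_replaces_outlier_with_local_median():
    x = np.sin(np.linspace(0, 3, 60))
    x[30] += 5.0
    filtered = bh.hampel_filter(x, n_neighbors=10, n_sigmas=1.0)
    window = x[20:41]
    assert filtered[30] == pytest.approx(np.median(window))
    # interior points far from the outlier are untouched (edges may be
    # adjusted: asymmetric windows on a trending series deviate > 1 MAD)
    assert np.allclose(filtered[45:50], x[45:50])


# ---------------------------------------------------------------------------
# behavior / activity correlation
# ---------------------------------------------------------------------------

def test_identical_trace_flagged():
    rng = np.random.default_rng(0)
    y = rng.normal(size=200)
    df, frac = bh.behavior_activity_correlation(y[None, :], y)
    assert df.loc[0, "r"] == pytest.approx(1.0)
    assert bool(df.loc[0, "significant"])


def test_null_flagged_fraction_below_joint_alpha():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(100, 300))
    y = rng.normal(size=300)
    _, frac = bh.behavior_activity_correlation(X, y)
    assert frac < 0.05


def test_constant_trace_excluded():
    rng = np.random.default_rng(2)
    X = np.vstack([np.ones(50), rng.normal(size=50)])
    y = rng.normal(size=50)
    df, _ = bh.behavior_activity_correlation(X, y)
    assert np.isnan(df.loc[0, "r"])
    assert not bool(df.loc[0, "significant"])


def test_too_few_samples_error():
    with pytest.raises(ValueError):
        bh.behavior_activity_correlation(np.zeros((2, 2)), np.zeros(2))
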