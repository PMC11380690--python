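"""Behavioral metrics for the Go/Nogo reversal task.

Outcome classification, signal-detection d-prime, learning-phase detection,
anticipatory-lick quantification, pupil geometry, and correlations between
behavioral traces and single-cell activity.

d' = Z(hit ratio) - Z(false-alarm ratio), where Z is the standard-normal
inverse CDF, the hit ratio is Hits/(Hits+Misses), and the false-alarm ratio
pools Nogo and catch trials: FAs/(FAs+CRs). Ratios of exactly 0 or 1 are
adjusted to 1/(2N) and 1 - 1/(2N) before the inverse CDF (the standard
log-linear correction), keeping d' finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("popact")

#: spout contacts within this many seconds of response-window onset are
#: treated as accidental touches, not responses
RESPONSE_GRACE_S = 0.2

EXPERT_DPRIME = 1.5
EXPERT_RUN = 3


@dataclass
class BehaviorSummary:
    """Per-session outcome counts and derived performance."""

    hits: int
    misses: int
    fas: int
    crs: int
    hit_ratio: float
    fa_ratio: float
    d_prime: float
    anticipatory_counts: np.ndarray | None = None


def licked_in_response_window(
    lick_times, window_onset_s: float, window_dur_s: float,
    grace_s: float = RESPONSE_GRACE_S,
) -> bool:
    """True if any lick falls in [onset + grace, onset + duration)."""
    licks = np.atleast_1d(np.asarray(lick_times, dtype=float))
    return bool(
        np.any((licks >= window_onset_s + grace_s) & (licks < window_onset_s + window_dur_s))
    )


def classify_outcome(trial_type: str, licked: bool) -> str:
    table = {
        ("Go", True): "Hit",
        ("Go", False): "Miss",
        ("Nogo", True): "FA",
        ("Nogo", False): "CR",
        ("catch", True): "catch-FA",
        ("catch", False): "catch-CR",
    }
    key = (trial_type, bool(licked))
    if key not in table:
        raise ValueError(f"unknown trial type '{trial_type}'")
    return table[key]


def _adjust_ratio(k: int, n: int) -> float:
    """Rate k/n with 0 -> 1/(2n) and 1 -> 1 - 1/(2n)."""
    r = k / n
    if r == 0.0:
        return 1.0 / (2 * n)
    if r == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return r


def d_prime(hits: int, misses: int, fas: int, crs: int) -> float:
    """Discriminability index from pooled outcome counts.

    Nogo and catch outcomes are pooled by the caller into fas/crs.
    """
    n_go = hits + misses
    n_nogo = fas + crs
    if n_go < 1 or n_nogo < 1:
        raise ValueError("need at least one Go and one Nogo/catch trial")
    hr = _adjust_ratio(hits, n_go)
    fr = _adjust_ratio(fas, n_nogo)
    return float(stats.norm.ppf(hr) - stats.norm.ppf(fr))


def summarize_session(trials: pd.DataFrame) -> BehaviorSummary:
    """Outcome counts and d' for one trial table (Nogo + catch pooled)."""
    counts = trials["outcome"].value_counts()
    hits = int(counts.get("Hit", 0))
    misses = int(counts.get("Miss", 0))
    fas = int(counts.get("FA", 0)) + int(counts.get("catch-FA", 0))
    crs = int(counts.get("CR", 0)) + int(counts.get("catch-CR", 0))
    hr = _adjust_ratio(hits, hits + misses)
    fr = _adjust_ratio(fas, fas + crs)
    return BehaviorSummary(
        hits=hits, misses=misses, fas=fas, crs=crs,
        hit_ratio=hr, fa_ratio=fr, d_prime=d_prime(hits, misses, fas, crs),
    )


def learning_phases(
    dprime_series,
    threshold: float = EXPERT_DPRIME,
    run_length: int = EXPERT_RUN,
    n_naive: int = 3,
):
    """Split a d' trajectory into naive / expert session sets.

    Expert onset is the first index ending a run of ``run_length``
    consecutive sessions with d' > threshold (None if never reached). The
    naive set is the first up-to-``n_naive`` sessions that are themselves
    below threshold; the expert set is every session above threshold.
    """
    d = np.asarray(dprime_series, dtype=float)
    if d.size < run_length:
        raise ValueError(f"need at least {run_length} sessions")
    above = d > threshold
    onset = None
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= run_length:
            onset = i
            break
    naive = [i for i in range(min(n_naive, d.size)) if not above[i]]
    expert = np.flatnonzero(above).tolist()
    return naive, expert, onset


def anticipatory_licks(
    lick_times,
    delay_windows,
    bin_s: float = 1.0 / 30.0,
):
    """Delay-period lick counts per trial and lick probability per time bin.

    ``delay_windows`` is a sequence of (start_s, end_s); licks are counted in
    the half-open interval [start, end). The per-bin probability is the
    fraction of trials with at least one lick in that bin (bins relative to
    delay onset).
    """
    licks = np.sort(np.atleast_1d(np.asarray(lick_times, dtype=float)))
    windows = np.asarray(delay_windows, dtype=float)
    if windows.ndim != 2 or windows.shape[1] != 2:
        raise ValueError("delay_windows must be (n_trials, 2)")
    counts = np.array(
        [np.count_nonzero((licks >= lo) & (licks < hi)) for lo, hi in windows],
        dtype=int,
    )
    dur = float(np.max(windows[:, 1] - windows[:, 0])) if len(windows) else 0.0
    n_bins = max(int(np.ceil(dur / bin_s)), 1)
    hit_bins = np.zeros((len(windows), n_bins), dtype=bool)
    for t, (lo, hi) in enumerate(windows):
        rel = licks[(licks >= lo) & (licks < hi)] - lo
        idx = np.minimum((rel / bin_s).astype(int), n_bins - 1)
        hit_bins[t, idx] = True
    prob = hit_bins.mean(axis=0) if len(windows) else np.zeros(n_bins)
    return counts, prob


def moving_average(x, n: int = 5):
    """Centered moving average with shrinking edge windows (MATLAB movmean)."""
    x = np.asarray(x, dtype=float)
    half_lo = (n - 1) // 2
    half_hi = n // 2
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = x[max(0, i - half_lo): i + half_hi + 1].mean()
    return out


# ---------------------------------------------------------------------------
# Pupil geometry
# ---------------------------------------------------------------------------

def fit_circle(points: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit.

    Solves ``x^2 + y^2 = 2ax + 2by + c`` in the least-squares sense and
    returns (cx, cy, r). Requires >= 3 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    (cx, cy, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = np.sqrt(c + cx**2 + cy**2)
    return float(cx), float(cy), float(r)


def hampel_filter(x, n_neighbors: int = 10, n_sigmas: float = 1.0):
    """Replace local outliers by the window median.

    Window = ``n_neighbors`` samples on each side; an outlier deviates from
    the window median by more than ``n_sigmas`` scaled MADs. NaNs are left
    in place and ignored when computing window statistics.
    """
    x = np.asarray(x, dtype=float)
    out = x.copy()
    k = 1.4826
    for i in range(x.size):
        if np.isnan(x[i]):
            continue
        window = x[max(0, i - n_neighbors): i + n_neighbors + 1]
        window = window[~np.isnan(window)]
        if window.size == 0:
            continue
        med = np.median(window)
        sigma = k * np.median(np.abs(window - med))
        if np.abs(x[i] - med) > n_sigmas * sigma:
            out[i] = med
    return out


def pupil_area(pupil_points: np.ndarray, n_neighbors: int = 10, n_sigmas: float = 1.0):
    """Per-frame pupil area from labeled edge points.

    Frames with fewer than 3 visible points get NaN. A circle is fit per
    frame, area = pi * r^2, and the series is Hampel-filtered.
    """
    pts = np.asarray(pupil_points, dtype=float)
    n_frames = pts.shape[0]
    area = np.full(n_frames, np.nan)
    for f in range(n_frames):
        visible = pts[f][~np.isnan(pts[f]).any(axis=1)]
        if visible.shape[0] >= 3:
            _, _, r = fit_circle(visible)
            area[f] = np.pi * r**2
    return hampel_filter(area, n_neighbors=n_neighbors, n_sigmas=n_sigmas)


# ---------------------------------------------------------------------------
# Behavior / activity correlation
# ---------------------------------------------------------------------------

def behavior_activity_correlation(
    cell_traces: np.ndarray,
    behavior_trace: np.ndarray,
    mask: np.ndarray | None = None,
    r_threshold: float = 0.2,
    alpha: float = 0.05,
):
    """Per-cell Pearson r against a behavioral trace on a shared 5 Hz clock.

    A cell is flagged significant iff |r| > ``r_threshold`` AND p < ``alpha``
    (two-sided p via the t transform). Constant cells are excluded with a
    logged count. Returns a DataFrame (cell, r, p, significant) and the
    flagged fraction among testable cells.
    """
    X = np.atleast_2d(np.asarray(cell_traces, dtype=float))
    y = np.asarray(behavior_trace, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        X, y = X[:, mask], y[mask]
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 masked samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = Xc.std(axis=1)
    sy = yc.std()
    testable = (sx > 0) & (sy > 0)
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("behavior correlation: excluded %d constant traces", n_excluded)
    r = np.full(X.shape[0], np.nan)
    r[testable] = (Xc[testable] @ yc) / (n * sx[testable] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    sig = (np.abs(r) > r_threshold) & (p < alpha) & testable
    df = pd.DataFrame({
        "cell": np.arange(X.shape[0]),
        "r": r,
        "p": p,
        "significant": sig,
    })
    frac = float(sig.sum() / max(testable.sum(), 1))
    return df, frac
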