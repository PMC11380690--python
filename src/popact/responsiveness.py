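"""Two-step stimulus-responsiveness classification.

Step 1: a two-sided Wilcoxon signed-rank test asks whether a cell's
per-trial mean response (z units, trial-baselined) differs from zero.
Step 2: cells passing the test are thresholded on the median response:
excited if median > +0.2 z, inhibited if median < -0.2 z. For auditory
trials the test is run both on the full 2 s stimulus window and on a 0.3 s
onset window to catch fast-adapting cells; passing either counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger("popact")

ALPHA = 0.05
MEDIAN_THRESHOLD = 0.2


@dataclass
class WindowTest:
    p: float
    median: float
    call: str  # excited | inhibited | nonresponsive


@dataclass
class ResponsivenessCall:
    call: str
    windows: dict = field(default_factory=dict)
    reason: str = ""


EXACT_MAX_N = 25


def _exact_signed_rank_p(x: np.ndarray) -> float:
    """Exact two-sided signed-rank p by dynamic programming over sign flips.

    Handles midranked ties exactly (ranks are doubled to stay on an integer
    grid). The null enumerates all 2^n sign assignments; two-sided
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    ranks = stats.rankdata(np.abs(x))
    scaled = np.round(2 * ranks).astype(int)
    w_obs = int(scaled[x > 0].sum())
    total = int(scaled.sum())
    ways = np.zeros(total + 1)
    ways[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(ways)
        shifted[r:] = ways[:-r] if r > 0 else ways
        ways = ways + shifted
    ways /= 2.0 ** len(scaled)
    p_le = ways[: w_obs + 1].sum()
    p_ge = ways[w_obs:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def signed_rank_p(x) -> float:
    """Two-sided Wilcoxon signed-rank p of a sample against zero.

    Zero differences are dropped (wilcox convention); ties midranked. Up to
    n = 25 the exact tie-aware null distribution is used (full enumeration
    by dynamic programming); beyond that, the normal approximation.
    """
    x = np.asarray(x, dtype=float)
    x = x[x != 0]
    if x.size == 0:
        raise ValueError("signed-rank undefined: all differences are zero")
    if x.size <= EXACT_MAX_N:
        return _exact_signed_rank_p(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(x, zero_method="wilcox", alternative="two-sided",
                             method="approx")
    return float(res.pvalue)


def classify_window(
    per_trial, alpha: float = ALPHA, threshold: float = MEDIAN_THRESHOLD
) -> WindowTest:
    x = np.asarray(per_trial, dtype=float)
    med = float(np.median(x))
    if np.all(x == 0):
        return WindowTest(p=1.0, median=med, call="nonresponsive")
    p = signed_rank_p(x)
    call = "nonresponsive"
    if p < alpha:
        if med > threshold:
            call = "excited"
        elif med < -threshold:
            call = "inhibited"
    return WindowTest(p=p, median=med, call=call)


def classify_cell(
    windows, alpha: float = ALPHA, threshold: float = MEDIAN_THRESHOLD,
    min_trials: int = 5,
) -> ResponsivenessCall:
    """Classify one cell from per-trial mean responses in one or more windows.

    ``windows`` maps a window label (e.g. "stimulus-2s", "onset-0.3s") to the
    per-trial mean response array. The cell is responsive if any window
    passes both steps; the sign comes from the first passing window in
    insertion order (full-window first by convention).
    """
    if not windows:
        raise ValueError("no windows supplied")
    results = {}
    call = "nonresponsive"
    reason = ""
    for label, per_trial in windows.items():
        x = np.asarray(per_trial, dtype=float)
        if x.size < min_trials:
            raise ValueError(f"window '{label}': need >= {min_trials} trials, got {x.size}")
        if np.all(x == 0):
            results[label] = WindowTest(p=1.0, median=0.0, call="nonresponsive")
            reason = "all-zero responses: signed-rank undefined"
            logger.info("classify_cell: %s in window '%s'", reason, label)
            continue
        results[label] = classify_window(x, alpha, threshold)
    for label, wt in results.items():
        if wt.call != "nonresponsive":
            call = wt.call
            break
    return ResponsivenessCall(call=call, windows=results, reason=reason)


def label_by_trial_type(go_call: ResponsivenessCall, nogo_call: ResponsivenessCall) -> str:
    """Go / Nogo / both / none label from the two per-trial-type calls."""
    go = go_call.call != "nonresponsive"
    nogo = nogo_call.call != "nonresponsive"
    if go and nogo:
        return "both"
    if go:
        return "Go"
    if nogo:
        return "Nogo"
    return "none"


def population_proportions(labels) -> dict:
    labels = list(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("no cells")
    return {lab: labels.count(lab) / n for lab in ("Go", "Nogo", "both", "none")}


def classify_session(z_traces, trials, onset_s: float = 0.3,
                     alpha: float = ALPHA, threshold: float = MEDIAN_THRESHOLD):
    """Per-cell Go/Nogo responsiveness labels for one session.

    ``z_traces`` is the z-scored conditioned trace set; the per-trial
    response is the mean z-score over the 2 s stimulus window (no further
    per-trial baseline). The fast-adapting 0.3 s onset window is evaluated
    only for trial types whose cue is auditory (stimulus label starts with
    "tone"). Returns a DataFrame with one row per cell: go_call, nogo_call,
    label.
    """
    import pandas as pd

    from .preprocess import epoch_and_baseline

    onsets = trials["onset_frame"].to_numpy()
    tens = epoch_and_baseline(z_traces, onsets, window="stimulus", baseline="none")
    fr = tens.frame_rate
    n_onset = int(round(onset_s * fr))

    rows = []
    masks = {}
    for ttype in ("Go", "Nogo"):
        mask = (trials["trial_type"] == ttype).to_numpy()
        stim = trials.loc[mask, "stimulus"]
        auditory = bool(len(stim)) and str(stim.iloc[0]).startswith("tone")
        masks[ttype] = (mask, auditory)
    for c in range(tens.n_cells):
        calls = {}
        for ttype, (mask, auditory) in masks.items():
            windows = {"stimulus-2s": tens.values[mask, c, :].mean(axis=1)}
            if auditory:
                windows["onset-0.3s"] = tens.values[mask, c, :n_onset].mean(axis=1)
            calls[ttype] = classify_cell(windows, alpha=alpha, threshold=threshold)
        rows.append({
            "cell": c,
            "go_call": calls["Go"].call,
            "nogo_call": calls["Nogo"].call,
            "label": label_by_trial_type(calls["Go"], calls["Nogo"]),
        })
    return pd.DataFrame(rows)


def proportion_transition_test(counts_a, counts_b):
    """Pearson chi-square on a 2 x K table of pooled cell-category counts.

    Returns (statistic, p, dof). Categories with expected count < 1 trigger
    a warning; fewer than two categories is an error (zero df).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts must be 1-D and the same length")
    table = np.vstack([a, b])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise ValueError("chi-square needs at least two categories (df >= 1)")
    stat, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        warnings.warn("chi-square expected cell count below 1", stacklevel=2)
    return float(stat), float(p), int(dof)
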