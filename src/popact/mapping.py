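"""Off-task sensory-mapping analyses.

Mapping sessions present 5 pure-tone frequencies (4, 8, 12, 16, 20 kHz),
4 drifting-grating directions, and all 20 audio-visual combinations, 8
repetitions each, in pseudo-random order. Analyses here: split-half
stimulus responsiveness, per-cell frequency tuning matrices and their
k-means clustering (correlation distance), pre/post tuning stability, the
multisensory integration index |AV| / |A + V|, and cross-session single-cell
PSTH correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .responsiveness import classify_cell, ResponsivenessCall
from . import clustering as _clustering

logger = logging.getLogger("popact")

FREQUENCIES_KHZ = (4, 8, 12, 16, 20)
DIRECTIONS = ("up", "down", "left", "right")


@dataclass
class MultisensoryIndexRecord:
    cell: int
    frequency_khz: float
    A: float
    V: float
    AV: float
    index: float | None
    exclusion: str  # none | both-nonsignificant | sign-conflict | zero-denominator


def split_half_points(stim_tensor_values: np.ndarray, frame_rate: float) -> np.ndarray:
    """Two data points per trial: means over the 0-1 s and 1-2 s halves.

    Input is (trials, frames) for one cell and stimulus (or
    (trials, cells, frames)); output doubles the trial axis.
    """
    vals = np.asarray(stim_tensor_values, dtype=float)
    half = int(round(1.0 * frame_rate))
    first = vals[..., :half].mean(axis=-1)
    second = vals[..., half: 2 * half].mean(axis=-1)
    return np.concatenate([first, second], axis=0)


def split_half_responsiveness(
    per_stimulus_values: dict,
    frame_rate: float,
    alpha: float = 0.05,
    threshold: float = 0.2,
) -> dict:
    """Split-half two-step responsiveness call per stimulus.

    ``per_stimulus_values`` maps stimulus label -> (trials, frames) response
    window array for one cell. Each trial contributes its 0-1 s and 1-2 s
    means as separate data points to the signed-rank + median-threshold
    classifier.
    """
    calls = {}
    for stim, vals in per_stimulus_values.items():
        points = split_half_points(vals, frame_rate)
        calls[stim] = classify_cell({"split-half": points}, alpha=alpha,
                                    threshold=threshold, min_trials=5)
    return calls


def overall_call(calls: dict) -> str:
    """Excited/inhibited if responsive to any stimulus, else nonresponsive."""
    for c in calls.values():
        if c.call == "excited":
            return "excited"
    for c in calls.values():
        if c.call == "inhibited":
            return "inhibited"
    return "nonresponsive"


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------

TUNING_BLOCKS = ("pre-multi", "post-multi", "pre-uni", "post-uni")


def tuning_matrix(records: dict) -> np.ndarray:
    """Cells x 20 tuning feature matrix.

    ``records`` maps each of the four blocks ("pre-multi", "post-multi",
    "pre-uni", "post-uni") to a (cells, 5) array of mean stimulus responses
    per frequency (multisensory responses already averaged over grating
    directions). Column order is the block order with frequencies ascending
    within each block. Cells with any non-finite feature are dropped.
    """
    missing = [b for b in TUNING_BLOCKS if b not in records]
    if missing:
        raise ValueError(f"missing tuning blocks: {missing}")
    mats = []
    for block in TUNING_BLOCKS:
        m = np.asarray(records[block], dtype=float)
        if m.ndim != 2 or m.shape[1] != len(FREQUENCIES_KHZ):
            raise ValueError(f"block '{block}' must be (cells, 5)")
        mats.append(m)
    X = np.hstack(mats)
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        logger.info("tuning_matrix: dropped %d cells with missing features",
                    int((~keep).sum()))
    return X[keep]


def cluster_tuning(X: np.ndarray, k: int = 8, seed: int = 0, n_restarts: int = 20):
    """K-means on tuning rows under correlation distance.

    Correlation distance equals cosine distance after row centering, so rows
    are mean-centered and clustered with the spherical k-means core.
    Returns (assignments, inertia).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} rows")
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.any(np.linalg.norm(Xc, axis=1) == 0):
        raise ValueError("constant tuning rows have undefined correlation distance")
    Xn = _clustering._normalize_rows(Xc)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        assign, inertia = _clustering._cosine_kmeans_once(Xn, k, rng)
        if best is None or inertia < best[1]:
            best = (assign, inertia)
    return best


def tuning_stability(pre: np.ndarray, post: np.ndarray):
    """Per-cell Pearson r between 5-point pre and post tuning curves.

    Constant curves have undefined correlation and yield NaN (logged count).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre/post shapes differ")
    r = np.full(pre.shape[0], np.nan)
    n_excluded = 0
    for i in range(pre.shape[0]):
        if pre[i].std() == 0 or post[i].std() == 0:
            n_excluded += 1
            continue
        r[i] = np.corrcoef(pre[i], post[i])[0, 1]
    if n_excluded:
        logger.info("tuning_stability: excluded %d constant curves", n_excluded)
    return r


def compare_stability(r_uni, r_multi):
    """Two-sample KS test between uni- and multisensory stability distributions."""
    a = np.asarray(r_uni, dtype=float)
    b = np.asarray(r_multi, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Multisensory index
# ---------------------------------------------------------------------------

def multisensory_index(
    A: float, V: float, AV: float,
    a_significant: bool = True, av_significant: bool = True,
    cell: int = -1, frequency_khz: float = np.nan,
) -> MultisensoryIndexRecord:
    """Index_f = |AV| / |A + V| with the stated exclusion rules.

    Excluded when (a) neither the auditory nor the audio-visual response is
    significant, (b) AV and A+V have opposite signs, or (c) A + V = 0.
    """
    rec = dict(cell=cell, frequency_khz=frequency_khz, A=float(A), V=float(V),
               AV=float(AV))
    if not (a_significant or av_significant):
        return MultisensoryIndexRecord(**rec, index=None, exclusion="both-nonsignificant")
    s = A + V
    if s == 0:
        return MultisensoryIndexRecord(**rec, index=None, exclusion="zero-denominator")
    if AV * s < 0:
        return MultisensoryIndexRecord(**rec, index=None, exclusion="sign-conflict")
    return MultisensoryIndexRecord(**rec, index=abs(AV) / abs(s), exclusion="none")


def index_table(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def ks2d2s(points_a: np.ndarray, points_b: np.ndarray, seed: int = 0,
           n_perm: int = 500):
    """Two-sample two-dimensional KS test (Fasano-Franceschini style).

    The statistic is the maximum over both samples' points of the difference
    in quadrant fractions; the p-value comes from a label permutation null.
    Returns (statistic, p).
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("inputs must be (n, 2) point sets")

    def quadrant_stat(a, b):
        centers = np.vstack([a, b])
        d = 0.0
        for cx, cy in centers:
            for sx in (True, False):
                for sy in (True, False):
                    xa = (a[:, 0] > cx) if sx else (a[:, 0] <= cx)
                    ya = (a[:, 1] > cy) if sy else (a[:, 1] <= cy)
                    xb = (b[:, 0] > cx) if sx else (b[:, 0] <= cx)
                    yb = (b[:, 1] > cy) if sy else (b[:, 1] <= cy)
                    d = max(d, abs((xa & ya).mean() - (xb & yb).mean()))
        return d

    stat = quadrant_stat(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.vstack([a, b])
    na = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        if quadrant_stat(pooled[perm[:na]], pooled[perm[na:]]) >= stat:
            count += 1
    return float(stat), float((count + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Cross-session PSTH correlation
# ---------------------------------------------------------------------------

def cross_session_psth_correlation(psth_pre: np.ndarray, psth_post: np.ndarray):
    """Per-cell Pearson r between pre and post concatenated PSTHs.

    Inputs are (cells, time) on a common base (stimulus conditions
    concatenated). Constant PSTHs are excluded. Returns (per-cell r, mean,
    SEM) over the defined cells.
    """
    pre = np.asarray(psth_pre, dtype=float)
    post = np.asarray(psth_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("PSTH shapes differ")
    r = np.full(pre.shape[0], np.nan)
    for i in range(pre.shape[0]):
        if pre[i].std() > 0 and post[i].std() > 0:
            r[i] = np.corrcoef(pre[i], post[i])[0, 1]
    valid = np.isfinite(r)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("psth correlation: excluded %d constant cells", n_excluded)
    vals = r[valid]
    mean = float(vals.mean()) if vals.size else np.nan
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
    return r, mean, sem
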