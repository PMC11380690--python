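"""Fluorescence conditioning and trial epoching.

The fixed signal path is: neuropil correction (F - 0.7 * Fneu), linear
detrend + zero-phase low-pass at 5 Hz, optional per-cell z-scoring against
the whole-session trace, then epoching into trial-aligned tensors under one
of several baseline conventions. Each stage stamps its name into the trace's
provenance so out-of-order calls fail loudly instead of silently producing
traces in the wrong units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger("popact")

#: canonical stage order; an operation refuses to run after a later stage
_STEP_ORDER = ("neuropil_correct", "condition", "zscore")

#: baseline conventions: window (seconds) measured back from the reference
#: point. Pre-stimulus windows reference the stimulus onset; the 150 ms
#: window references the delay onset.
BASELINE_WINDOWS = {
    "pre-stim-0.5s": 0.5,
    "pre-stim-1s": 1.0,
    "pre-stim-2s": 2.0,
    "pre-delay-150ms": 0.15,
    "none": None,
}

WINDOW_LABELS = ("stimulus", "delay", "response", "baseline")


@dataclass
class Traces:
    """Cell-by-frame trace matrix with processing provenance."""

    values: np.ndarray
    frame_rate: float
    steps: tuple = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[None, :]
        if not np.all(np.isfinite(self.values)):
            raise ValueError("traces contain non-finite values")

    def _check_order(self, step: str) -> None:
        idx = _STEP_ORDER.index(step)
        for done in self.steps:
            if done in _STEP_ORDER and _STEP_ORDER.index(done) >= idx:
                raise ValueError(
                    f"step '{step}' cannot follow '{done}' "
                    f"(pipeline order is {' -> '.join(_STEP_ORDER)})"
                )

    def _with(self, values: np.ndarray, step: str, **params) -> "Traces":
        merged = dict(self.params)
        merged[step] = params
        return Traces(values, self.frame_rate, self.steps + (step,), merged)


@dataclass
class TrialEpochTensor:
    """(trials, cells, frames-in-window) tensor under one baseline convention."""

    values: np.ndarray
    window: str
    baseline: str
    frame_rate: float
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("epoch tensor must be 3-D (trials, cells, frames)")
        if self.baseline not in BASELINE_WINDOWS:
            raise ValueError(f"unknown baseline convention '{self.baseline}'")
        if self.trial_index is None:
            self.trial_index = np.arange(self.values.shape[0])

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def preprocess_session(rec, zscore: bool = False, coefficient: float = 0.7,
                       cutoff_hz: float = 5.0):
    """Standard signal path for a session recording.

    Neuropil correction, detrend + 5 Hz low-pass, optionally per-cell
    z-scoring. Returns the Traces (and the kept-cell mask when z-scoring).
    """
    tr = neuropil_correct(rec.F, rec.Fneu, coefficient=coefficient,
                          frame_rate=rec.frame_rate)
    tr = condition_trace(tr, cutoff_hz=cutoff_hz)
    if zscore:
        return zscore_cells(tr)
    return tr


def frames(duration_s: float, frame_rate: float) -> int:
    """Window length in frames: round(duration * rate), half-open windows."""
    return int(round(duration_s * frame_rate))


def neuropil_correct(
    F: np.ndarray, Fneu: np.ndarray, coefficient: float = 0.7, frame_rate: float = 30.0
) -> Traces:
    """Subtract the scaled neuropil signal: corrected = F - coefficient * Fneu."""
    F = np.asarray(F, dtype=float)
    Fneu = np.asarray(Fneu, dtype=float)
    if F.shape != Fneu.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs Fneu {Fneu.shape}")
    out = Traces(F - coefficient * Fneu, frame_rate)
    return out._with(out.values, "neuropil_correct", coefficient=coefficient)


def _as_traces(traces, frame_rate=None) -> Traces:
    if isinstance(traces, Traces):
        return traces
    if frame_rate is None:
        raise ValueError("frame_rate required when passing a bare array")
    return Traces(traces, frame_rate)


def condition_trace(
    traces, cutoff_hz: float = 5.0, order: int = 4, frame_rate: float | None = None
) -> Traces:
    """Linear detrend then zero-phase Butterworth low-pass at ``cutoff_hz``.

    Length is preserved (filtfilt). Requires frame_rate > 2 * cutoff.
    """
    tr = _as_traces(traces, frame_rate)
    tr._check_order("condition")
    nyq = tr.frame_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    detrended = signal.detrend(tr.values, axis=1, type="linear")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=tr.frame_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, detrended, axis=1)
    return tr._with(filtered, "condition", cutoff_hz=cutoff_hz, order=order)


def downsample(values, frame_rate: float, target_hz: float):
    """Decimate by frame averaging to ``target_hz``.

    Averaging over non-overlapping blocks acts as the anti-alias filter.
    Returns ``(downsampled, target_hz, bin_centers_s)``; a trailing partial
    block is dropped.
    """
    if target_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_hz >= frame_rate:
        raise ValueError("target rate must be below the frame rate")
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[None, :]
    factor = int(round(frame_rate / target_hz))
    n = (arr.shape[1] // factor) * factor
    ds = arr[:, :n].reshape(arr.shape[0], -1, factor).mean(axis=2)
    centers = (np.arange(ds.shape[1]) + 0.5) * factor / frame_rate
    if squeeze:
        ds = ds[0]
    return ds, frame_rate / factor, centers


def zscore_cells(traces, frame_rate: float | None = None):
    """Per-cell z-score against the whole-session trace.

    Zero-variance cells cannot be z-scored; they are excluded and logged.
    Returns ``(Traces, kept_mask)``.
    """
    tr = _as_traces(traces, frame_rate)
    tr._check_order("zscore")
    mu = tr.values.mean(axis=1, keepdims=True)
    sd = tr.values.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.info("zscore_cells: excluded %d zero-variance cells: %s",
                    (~keep).sum(), np.flatnonzero(~keep).tolist())
    z = (tr.values[keep] - mu[keep]) / sd[keep]
    return tr._with(z, "zscore"), keep


def epoch_and_baseline(
    traces,
    onset_frames: np.ndarray,
    window: str = "stimulus",
    baseline: str = "pre-stim-0.5s",
    frame_rate: float | None = None,
    stimulus_s: float = 2.0,
    delay_s: float = 2.0,
    response_s: float = 1.5,
) -> TrialEpochTensor:
    """Cut trial-aligned windows and subtract the per-trial baseline mean.

    ``onset_frames`` are stimulus-onset frames (0-based). Windows are
    half-open in frames: stimulus [onset, onset+2s), delay follows the
    stimulus, response follows the delay. The baseline convention determines
    the per-trial, per-cell scalar subtracted from the window.
    """
    tr = _as_traces(traces, frame_rate)
    fr = tr.frame_rate
    if window not in WINDOW_LABELS:
        raise ValueError(f"unknown window '{window}'")
    if baseline not in BASELINE_WINDOWS:
        raise ValueError(f"unknown baseline convention '{baseline}'")

    n_stim = frames(stimulus_s, fr)
    n_delay = frames(delay_s, fr)
    n_resp = frames(response_s, fr)
    offsets = {
        "baseline": (-frames(2.0, fr), 0),
        "stimulus": (0, n_stim),
        "delay": (n_stim, n_stim + n_delay),
        "response": (n_stim + n_delay, n_stim + n_delay + n_resp),
    }
    lo, hi = offsets[window]

    onsets = np.asarray(onset_frames, dtype=int)
    n_frames = tr.values.shape[1]
    starts = onsets + lo
    stops = onsets + hi
    bad = np.flatnonzero((starts < 0) | (stops > n_frames))
    if bad.size:
        raise ValueError(f"epoch window out of range for trials {bad.tolist()}")

    idx = starts[:, None] + np.arange(hi - lo)[None, :]
    tensor = tr.values[:, idx].transpose(1, 0, 2)  # trials, cells, frames

    if baseline != "none":
        dur = BASELINE_WINDOWS[baseline]
        nb = frames(dur, fr)
        # the 150 ms convention is anchored to the delay onset
        ref = onsets + n_stim if baseline == "pre-delay-150ms" else onsets
        bstarts = ref - nb
        if (bstarts < 0).any():
            bad = np.flatnonzero(bstarts < 0)
            raise ValueError(f"baseline window out of range for trials {bad.tolist()}")
        bidx = bstarts[:, None] + np.arange(nb)[None, :]
        base = tr.values[:, bidx].transpose(1, 0, 2).mean(axis=2, keepdims=True)
        tensor = tensor - base

    return TrialEpochTensor(tensor, window, baseline, fr)
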