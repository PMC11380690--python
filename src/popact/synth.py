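"""Synthetic Go/Nogo calcium-imaging experiments with known ground truth.

The generator emulates the task's trial structure — 140 trials per session
at a 30% Go / 35% Nogo / 35% catch mix, 2 s stimulus, 2 s delay, 1.5 s
response window, 6-13 s inter-trial intervals, ~30 Hz sampling — and plants
functional cell classes (stimulus-responsive, learning-modulated, delay
ramping, behavior-coupled) on top of GCaMP-like calcium kinetics, Gaussian
frame noise, linear drift, and a neuropil contamination term that the
standard 0.7-coefficient correction removes exactly.

Delay-period coherence is planted as a shared latent signal on Hit trials:
every cell carries a fixed positive loading onto a per-trial smooth latent,
scaled by ``delay_coherence[phase]``. This is the knob the population-vector
and co-activity analyses are calibrated against.

Amplitudes are expressed in units of the conditioned trace's noise scale
(approximately z units after session z-scoring).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .session_io import SessionRecording, BehavioralTraces, validate_trial_table
from .behavior import classify_outcome, licked_in_response_window

logger = logging.getLogger("popact")

CELL_CLASSES = (
    "stable-Go",
    "learning-enhanced",
    "learning-inhibited",
    "ramp-up",
    "ramp-down",
    "Nogo-responsive",
    "behavior-coupled",
    "nonresponsive",
)

PHASES = ("initial-naive", "initial-expert", "reversal-naive", "reversal-expert")

#: default class mix for a full experiment
DEFAULT_CLASS_PROBS = {
    "stable-Go": 0.10,
    "learning-enhanced": 0.10,
    "learning-inhibited": 0.05,
    "ramp-up": 0.10,
    "ramp-down": 0.05,
    "Nogo-responsive": 0.15,
    "behavior-coupled": 0.05,
    "nonresponsive": 0.40,
}

#: stated world for the population-vector coherence experiments: stimulus
#: responses identical across phases (so stimulus-epoch PVC stays flat) and
#: no systematic delay pattern other than the planted shared latent
COHERENCE_CLASS_PROBS = {
    "stable-Go": 0.20,
    "Nogo-responsive": 0.15,
    "nonresponsive": 0.65,
}

#: stated world for the co-activity network experiments: ramp cells present
#: so the ramp-removal control is exercisable
NETWORK_CLASS_PROBS = {
    "stable-Go": 0.15,
    "ramp-up": 0.10,
    "ramp-down": 0.05,
    "Nogo-responsive": 0.15,
    "nonresponsive": 0.55,
}

DEFAULT_EFFECT_SIZES = {
    "stable-Go": 1.5,
    "learning-enhanced": 1.5,
    "learning-inhibited": 1.5,
    "ramp-up": 1.0,
    "ramp-down": 1.0,
    "Nogo-responsive": 1.2,
    "behavior-coupled": 0.8,
    "nonresponsive": 0.0,
}

#: factor applied to learning-modulated classes in the naive phase
NAIVE_MODULATION = {"learning-enhanced": 0.2, "learning-inhibited": 1.0}
EXPERT_MODULATION = {"learning-enhanced": 1.0, "learning-inhibited": 0.2}

#: phase-dependent lick policy: (p_lick_go, p_lick_nogo, p_lick_catch)
LICK_POLICY = {
    "naive": (0.55, 0.50, 0.45),
    "expert": (0.90, 0.12, 0.10),
}

#: anticipatory licks during the 2 s delay (Poisson rate, Hz) on lick trials
ANTICIPATORY_RATE_HZ = {"naive": 0.3, "expert": 1.5}


@dataclass
class SimConfig:
    """Generator parameters. Defaults are the task's stated conditions."""

    n_mice: int = 8
    n_cells: int = 100
    sessions_per_phase: int = 3
    n_trials: int = 140
    trial_mix: tuple = (0.30, 0.35, 0.35)
    frame_rate_hz: float = 30.0
    stimulus_s: float = 2.0
    delay_s: float = 2.0
    response_s: float = 1.5
    iti_range_s: tuple = (6.0, 13.0)
    kernel_rise_s: float = 0.07
    kernel_decay_s: float = 1.7
    noise_sd: float = 1.0
    drift_sd: float = 0.3
    amplitude_jitter: float = 0.3
    response_prob: float = 0.6
    coherence_amplitude: float = 1.0
    delay_coherence: dict = field(default_factory=lambda: {
        "initial-naive": 0.0, "initial-expert": 0.4,
        "reversal-naive": 0.0, "reversal-expert": 0.4,
    })
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    # learning-curve parameters
    n_sessions: int = 14
    expert_crossing_session: int = 10
    dprime_max: float = 3.0
    dprime_tau: float = 1.5
    dprime_noise_sd: float = 0.15
    # mapping sessions
    mapping_reps: int = 8
    mapping_iti_range_s: tuple = (6.0, 9.0)
    multisensory_gain: float = 1.0
    tuning_width: float = 1.0

    def validate(self) -> "SimConfig":
        if abs(sum(self.trial_mix) - 1.0) > 1e-9:
            raise ValueError("trial_mix must sum to 1")
        if min(self.stimulus_s, self.delay_s, self.response_s) <= 0:
            raise ValueError("epoch durations must be positive")
        if self.frame_rate_hz <= 2 * 5.0:
            raise ValueError("frame rate must exceed twice the 5 Hz low-pass cutoff")
        if self.n_trials < len(self.trial_mix):
            raise ValueError("need at least one trial per type")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        return self


@dataclass
class GroundTruth:
    """What was planted: per-cell classes, coherence plan, amplitudes, seed."""

    cell_class_labels: np.ndarray
    planted_delay_coherence: dict
    planted_effect_sizes: dict
    seed: int
    loadings: np.ndarray | None = None          # delay-latent loadings per cell
    events_per_cell: np.ndarray | None = None   # stimulus transients planted


@dataclass
class MappingGroundTruth:
    seed: int
    pref_freq_idx: np.ndarray
    tuning_width: float
    aud_amp: np.ndarray
    vis_amp: np.ndarray          # (cells, 4) per-direction amplitude
    gain: np.ndarray             # multisensory gain per cell
    responsive: np.ndarray


def trial_type_counts(n_trials: int, trial_mix=(0.30, 0.35, 0.35)) -> tuple[int, int, int]:
    """Deterministic allocation: floor Go, floor Nogo, remainder to catch."""
    n_go = int(np.floor(trial_mix[0] * n_trials))
    n_nogo = int(np.floor(trial_mix[1] * n_trials))
    n_catch = n_trials - n_go - n_nogo
    if min(n_go, n_nogo, n_catch) < 1:
        raise ValueError("trial counts below 1 per type")
    return n_go, n_nogo, n_catch


def plant_ground_truth(config: SimConfig, seed: int) -> GroundTruth:
    """Assign cell classes (largest-remainder counts) and latent loadings."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_cells
    probs = config.class_probs
    counts = {c: int(np.floor(p * n)) for c, p in probs.items()}
    remainders = sorted(probs, key=lambda c: probs[c] * n - counts[c], reverse=True)
    short = n - sum(counts.values())
    for c in remainders[:short]:
        counts[c] += 1
    labels = np.array([c for c, k in counts.items() for _ in range(k)])
    labels = labels[rng.permutation(n)]
    loadings = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    return GroundTruth(
        cell_class_labels=labels,
        planted_delay_coherence=dict(config.delay_coherence),
        planted_effect_sizes=dict(config.effect_sizes),
        seed=seed,
        loadings=loadings,
    )


def calcium_kernel(config: SimConfig) -> np.ndarray:
    """Difference-of-exponentials kernel (rise 0.07 s, decay 1.7 s), peak 1."""
    fr = config.frame_rate_hz
    t = np.arange(0, 5 * config.kernel_decay_s, 1.0 / fr)
    k = (1.0 - np.exp(-t / config.kernel_rise_s)) * np.exp(-t / config.kernel_decay_s)
    return k / k.max()


def _response_shape(drive: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = np.convolve(drive, kernel)
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def _shapes(config: SimConfig) -> dict:
    """Peak-normalized trial-locked response templates."""
    fr = config.frame_rate_hz
    n_stim = int(round(config.stimulus_s * fr))
    n_delay = int(round(config.delay_s * fr))
    kernel = calcium_kernel(config)
    stim = _response_shape(np.ones(n_stim), kernel)
    onset = _response_shape(np.ones(int(round(0.3 * fr))), kernel)
    ramp_up = _response_shape(np.linspace(0, 1, n_delay), kernel)
    return {
        "stim": stim,
        "onset": onset,
        "ramp_up": ramp_up,
        "ramp_down": -ramp_up,
        "n_stim": n_stim,
        "n_delay": n_delay,
    }


def _policy_key(phase: str) -> str:
    return "expert" if phase.endswith("expert") else "naive"


def _make_trials(config: SimConfig, phase: str, rng: np.random.Generator):
    """Trial order, timing, licking, and outcomes for one session."""
    fr = config.frame_rate_hz
    n_go, n_nogo, n_catch = trial_type_counts(config.n_trials, config.trial_mix)
    types = np.array(["Go"] * n_go + ["Nogo"] * n_nogo + ["catch"] * n_catch)
    types = types[rng.permutation(config.n_trials)]

    trial_len = config.stimulus_s + config.delay_s + config.response_s
    itis = rng.uniform(*config.iti_range_s, size=config.n_trials)
    onsets_s = np.cumsum(itis) + np.arange(config.n_trials) * trial_len
    onset_frames = np.round(onsets_s * fr).astype(int)

    task_rule = "auditory-go" if phase.startswith("initial") else "visual-go"
    go_cue = "tone-12kHz" if task_rule == "auditory-go" else "grating-right"
    nogo_cue = "grating-right" if task_rule == "auditory-go" else "tone-12kHz"
    stim_map = {"Go": go_cue, "Nogo": nogo_cue, "catch": "blank"}
    stimuli = np.array([stim_map[t] for t in types])

    p_go, p_nogo, p_catch = LICK_POLICY[_policy_key(phase)]
    p = np.where(types == "Go", p_go, np.where(types == "Nogo", p_nogo, p_catch))
    will_lick = rng.random(config.n_trials) < p

    resp_onset = onsets_s + config.stimulus_s + config.delay_s
    delay_onset = onsets_s + config.stimulus_s
    antic_rate = ANTICIPATORY_RATE_HZ[_policy_key(phase)]

    lick_lists, outcomes = [], []
    for i in range(config.n_trials):
        licks = []
        if will_lick[i]:
            first = resp_onset[i] + 0.25 + rng.uniform(0.0, 0.9)
            licks.append(first)
            licks.extend(first + np.cumsum(rng.uniform(0.12, 0.3, size=rng.integers(0, 4))))
            k = rng.poisson(antic_rate * config.delay_s)
            licks.extend(delay_onset[i] + rng.uniform(0.0, config.delay_s, size=k))
        if rng.random() < 0.03:  # accidental spout touch inside the grace period
            licks.append(resp_onset[i] + rng.uniform(0.0, 0.19))
        licks = sorted(licks)
        licked = licked_in_response_window(licks, resp_onset[i], config.response_s)
        outcomes.append(classify_outcome(types[i], licked))
        lick_lists.append(np.array(licks))

    trials = pd.DataFrame({
        "trial": np.arange(config.n_trials),
        "trial_type": types,
        "stimulus": stimuli,
        "onset_frame": onset_frames,
        "outcome": outcomes,
        "lick_times": lick_lists,
        "rewarded": [o == "Hit" for o in outcomes],
    })
    return validate_trial_table(trials), task_rule


def generate_session(
    config: SimConfig,
    phase: str,
    seed: int,
    ground_truth: GroundTruth | None = None,
    mouse_id: str = "m0",
    session_id: str | None = None,
    noiseless: bool = False,
):
    """One complete synthetic session.

    Returns ``(SessionRecording, TrialTable, BehavioralTraces, GroundTruth)``.
    Passing the same ``ground_truth`` across sessions keeps a mouse's cell
    classes and latent loadings fixed (longitudinal tracking is then the
    identity map). ``noiseless=True`` suppresses noise, drift and amplitude
    jitter for oracle checks on the planted kinetics.
    """
    config.validate()
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    rng = np.random.default_rng(seed)
    if ground_truth is None:
        ground_truth = plant_ground_truth(config, seed)
    labels = ground_truth.cell_class_labels
    loadings = ground_truth.loadings
    fr = config.frame_rate_hz
    n_cells = config.n_cells

    trials, task_rule = _make_trials(config, phase, rng)
    onsets = trials["onset_frame"].to_numpy()
    shapes = _shapes(config)
    n_stim, n_delay = shapes["n_stim"], shapes["n_delay"]
    n_frames = int(onsets[-1] + round((config.stimulus_s + config.delay_s
                                       + config.response_s + 2.0) * fr))

    sig = np.zeros((n_cells, n_frames), dtype=np.float32)
    events = np.zeros(n_cells, dtype=int)
    jitter_sd = 0.0 if noiseless else config.amplitude_jitter

    go_idx = np.flatnonzero((trials["trial_type"] == "Go").to_numpy())
    nogo_idx = np.flatnonzero((trials["trial_type"] == "Nogo").to_numpy())
    hit_idx = np.flatnonzero((trials["outcome"] == "Hit").to_numpy())
    key = _policy_key(phase)
    naive = key == "naive"

    p_respond = 1.0 if noiseless else config.response_prob

    def add_shape(cell, trial_idx, shape, amp, offset=0):
        for t in trial_idx:
            if rng.random() > p_respond:
                continue
            start = onsets[t] + offset
            stop = min(start + shape.size, n_frames)
            a = amp * max(1.0 + jitter_sd * rng.standard_normal(), 0.0)
            sig[cell, start:stop] += a * shape[: stop - start]

    amps = ground_truth.planted_effect_sizes
    for cell in range(n_cells):
        lab = labels[cell]
        if lab in ("stable-Go", "learning-enhanced", "learning-inhibited"):
            mod = (NAIVE_MODULATION if naive else EXPERT_MODULATION).get(lab, 1.0)
            amp = amps[lab] * mod
            if amp > 0:
                add_shape(cell, go_idx, shapes["stim"], amp)
                events[cell] += go_idx.size
        elif lab == "Nogo-responsive":
            add_shape(cell, nogo_idx, shapes["stim"], amps[lab])
            events[cell] += nogo_idx.size
        elif lab == "ramp-up":
            add_shape(cell, hit_idx, shapes["ramp_up"], amps[lab], offset=n_stim)
        elif lab == "ramp-down":
            add_shape(cell, hit_idx, shapes["ramp_down"], amps[lab], offset=n_stim)

    # Shared delay-period latent on rewarded trials, scaled by coherence.
    # The per-trial amplitude is positive (lognormal) so the loading pattern
    # recurs with the same sign on every rewarded trial; a smooth common
    # fluctuation rides on top so within-trial time series also co-vary.
    coherence = float(ground_truth.planted_delay_coherence.get(phase, 0.0))
    if coherence > 0 and hit_idx.size:
        amp_c = coherence * config.coherence_amplitude
        w = max(int(round(0.3 * fr)), 1)
        for t in hit_idx:
            a_t = rng.lognormal(mean=0.0, sigma=0.5)
            fluct = np.convolve(rng.standard_normal(n_delay), np.ones(w) / w,
                                mode="same")
            sd = fluct.std()
            if sd > 0:
                fluct = fluct / sd * 0.5
            latent = a_t * (1.0 + fluct)
            lo = onsets[t] + n_stim
            sig[:, lo: lo + n_delay] += (amp_c * loadings[:, None]
                                         * latent[None, :]).astype(np.float32)

    # behavioral traces
    locomotion = np.abs(sps.convolve(rng.standard_normal(n_frames),
                                     np.ones(15) / 15, mode="same")) * 3.0
    bcells = np.flatnonzero(labels == "behavior-coupled")
    if bcells.size:
        loco_z = (locomotion - locomotion.mean()) / locomotion.std()
        sig[bcells] += amps["behavior-coupled"] * loco_z[None, :]

    radius = 20.0 + sps.convolve(rng.standard_normal(n_frames),
                                 np.ones(60) / 60, mode="same") * 10.0
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    pupil = np.empty((n_frames, 8, 2))
    pupil[:, :, 0] = radius[:, None] * np.cos(angles)[None, :]
    pupil[:, :, 1] = radius[:, None] * np.sin(angles)[None, :]
    if not noiseless:
        pupil += rng.normal(0, 0.1, size=pupil.shape)
        lost = rng.random(n_frames) < 0.02
        pupil[lost, 2:, :] = np.nan  # tracker loses all but 2 points

    all_licks = np.sort(np.concatenate(list(trials["lick_times"])))
    behav = BehavioralTraces(locomotion=locomotion, pupil_points=pupil,
                             lick_times=all_licks, frame_rate=fr)

    # noise, drift, neuropil contamination (in place, float32)
    npil = np.zeros(n_frames, dtype=np.float32)
    if not noiseless:
        noise = rng.standard_normal(sig.shape, dtype=np.float32)
        noise *= config.noise_sd
        sig += noise
        del noise
        slope = rng.normal(0, config.drift_sd, size=(n_cells, 1)).astype(np.float32)
        sig += slope * np.linspace(-1, 1, n_frames, dtype=np.float32)[None, :]
        npil[:] = sps.convolve(rng.standard_normal(n_frames), np.ones(30) / 30,
                               mode="same") * 2.0

    Fneu = np.broadcast_to(50.0 + npil[None, :], sig.shape).copy()
    if not noiseless:
        neu_noise = rng.standard_normal(sig.shape, dtype=np.float32)
        neu_noise *= 0.05
        Fneu += neu_noise
        del neu_noise
    F = sig
    F += 100.0
    F += 0.7 * npil[None, :]

    rec = SessionRecording(
        F=F, Fneu=Fneu, frame_rate=fr, mouse_id=mouse_id,
        session_id=session_id or f"{mouse_id}-{phase}-{seed}",
        phase=phase, task_rule=task_rule,
    )
    gt = replace(ground_truth, events_per_cell=events)
    return rec, trials, behav, gt


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

@dataclass
class LearningCurve:
    dprime: np.ndarray
    hit_p: np.ndarray
    fa_p: np.ndarray
    deterministic: np.ndarray
    reversal_start: int


def _logistic_dprime(config: SimConfig, s: np.ndarray) -> np.ndarray:
    """Deterministic d' trajectory crossing 1.5 at the configured session."""
    c = config.expert_crossing_session
    s0 = c + config.dprime_tau * np.log(config.dprime_max / 1.5 - 1.0)
    return config.dprime_max / (1.0 + np.exp(-(s - s0) / config.dprime_tau))


def generate_learning_curve(config: SimConfig, seed: int) -> LearningCurve:
    """Per-session hit/FA probabilities and d' for initial + reversal learning.

    The deterministic backbone is a logistic in session index that crosses
    d' = 1.5 at ``expert_crossing_session``; reversal restarts the curve.
    With ``dprime_noise_sd = 0`` the output equals the backbone exactly.
    """
    config.validate()
    if config.n_sessions < 1:
        raise ValueError("need at least one session")
    rng = np.random.default_rng(seed)
    s = np.arange(config.n_sessions, dtype=float)
    det = _logistic_dprime(config, s)
    det = np.concatenate([det, det])  # reversal restarts the trajectory
    noise = (rng.normal(0, config.dprime_noise_sd, size=det.size)
             if config.dprime_noise_sd > 0 else 0.0)
    d = det + noise
    hit_p = stats.norm.cdf(d / 2.0)
    fa_p = stats.norm.cdf(-d / 2.0)
    return LearningCurve(dprime=d, hit_p=hit_p, fa_p=fa_p, deterministic=det,
                         reversal_start=config.n_sessions)


# ---------------------------------------------------------------------------
# Sensory-mapping sessions
# ---------------------------------------------------------------------------

FREQUENCIES_KHZ = (4, 8, 12, 16, 20)
DIRECTIONS = ("up", "down", "left", "right")


def mapping_catalog() -> pd.DataFrame:
    """The 29 enumerable stimulus types: 5 tones, 4 gratings, 20 pairs."""
    rows = []
    for f in FREQUENCIES_KHZ:
        rows.append(("auditory", f, ""))
    for d in DIRECTIONS:
        rows.append(("visual", np.nan, d))
    for f in FREQUENCIES_KHZ:
        for d in DIRECTIONS:
            rows.append(("multisensory", f, d))
    return pd.DataFrame(rows, columns=["modality", "frequency_khz", "direction"])


def plant_mapping_ground_truth(config: SimConfig, seed: int) -> MappingGroundTruth:
    rng = np.random.default_rng(seed)
    n = config.n_cells
    return MappingGroundTruth(
        seed=seed,
        pref_freq_idx=rng.integers(0, len(FREQUENCIES_KHZ), size=n),
        tuning_width=config.tuning_width,
        aud_amp=rng.uniform(1.0, 2.0, size=n),
        vis_amp=rng.uniform(0.3, 1.0, size=(n, len(DIRECTIONS))),
        gain=np.full(n, config.multisensory_gain),
        responsive=rng.random(n) < 0.8,
    )


def tuning_response(gt: MappingGroundTruth, cell: int, modality: str,
                    freq_idx: int | None, dir_idx: int | None) -> float:
    """Noiseless mean response amplitude of one cell to one stimulus."""
    if not gt.responsive[cell]:
        return 0.0
    A = 0.0
    if freq_idx is not None:
        A = gt.aud_amp[cell] * np.exp(
            -((freq_idx - gt.pref_freq_idx[cell]) ** 2) / (2 * gt.tuning_width**2)
        )
    V = gt.vis_amp[cell, dir_idx] if dir_idx is not None else 0.0
    if modality == "auditory":
        return float(A)
    if modality == "visual":
        return float(V)
    return float(gt.gain[cell] * (A + V))


def generate_mapping_session(
    config: SimConfig,
    seed: int,
    ground_truth: MappingGroundTruth | None = None,
    mouse_id: str = "m0",
    session_id: str | None = None,
    noiseless: bool = False,
):
    """One sensory-mapping session (stimulus catalog x 8 repetitions).

    Returns ``(SessionRecording, MappingTrialTable, MappingGroundTruth)``.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    if ground_truth is None:
        ground_truth = plant_mapping_ground_truth(config, seed)
    gt = ground_truth
    fr = config.frame_rate_hz

    catalog = mapping_catalog()
    trials = catalog.loc[catalog.index.repeat(config.mapping_reps)].reset_index(drop=True)
    trials = trials.iloc[rng.permutation(len(trials))].reset_index(drop=True)

    itis = rng.uniform(*config.mapping_iti_range_s, size=len(trials))
    onsets_s = np.cumsum(itis) + np.arange(len(trials)) * config.stimulus_s
    trials["trial"] = np.arange(len(trials))
    trials["onset_frame"] = np.round(onsets_s * fr).astype(int)

    onsets = trials["onset_frame"].to_numpy()
    n_frames = int(onsets[-1] + round((config.stimulus_s + 2.0) * fr))
    shapes = _shapes(config)
    freq_to_idx = {f: i for i, f in enumerate(FREQUENCIES_KHZ)}
    dir_to_idx = {d: i for i, d in enumerate(DIRECTIONS)}
    jitter_sd = 0.0 if noiseless else config.amplitude_jitter

    n_cells = config.n_cells
    sig = np.zeros((n_cells, n_frames))
    stim_shape = shapes["stim"]
    for t in range(len(trials)):
        row = trials.iloc[t]
        fi = freq_to_idx.get(row["frequency_khz"])
        di = dir_to_idx.get(row["direction"])
        amp = np.array([
            tuning_response(gt, c, row["modality"], fi, di) for c in range(n_cells)
        ])
        if jitter_sd:
            amp = amp * np.clip(1.0 + jitter_sd * rng.standard_normal(n_cells), 0, None)
        start = onsets[t]
        stop = min(start + stim_shape.size, n_frames)
        sig[:, start:stop] += amp[:, None] * stim_shape[None, : stop - start]

    if noiseless:
        noise = np.zeros_like(sig)
    else:
        noise = rng.normal(0, config.noise_sd, size=sig.shape)
        noise += rng.normal(0, config.drift_sd, size=(n_cells, 1)) \
            * np.linspace(-1, 1, n_frames)[None, :]
    Fneu = np.full_like(sig, 50.0)
    F = 100.0 + sig + noise

    rec = SessionRecording(
        F=F, Fneu=Fneu, frame_rate=fr, mouse_id=mouse_id,
        session_id=session_id or f"{mouse_id}-mapping-{seed}",
        phase="mapping", task_rule="none",
    )
    return rec, trials, gt


def write_ground_truth(gt: GroundTruth, path) -> str:
    """Structured text sidecar for a planted ground truth."""
    payload = {}
    for key, val in asdict(gt).items():
        payload[key] = val.tolist() if isinstance(val, np.ndarray) else val
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)
    return str(path)
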