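"""Synthetic-experiment generator: trial structure, determinism, planted classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from popact import preprocess as pp
from popact import population_vector as pv
from popact.synth import (
    SimConfig,
    generate_learning_curve,
    generate_mapping_session,
    generate_session,
    mapping_catalog,
    plant_ground_truth,
    trial_type_counts,
    tuning_response,
)
from popact.mapping import multisensory_index

from conftest import ZERO_COHERENCE, fast_config


def test_trial_mix_140_trials():
    assert trial_type_counts(140, (0.30, 0.35, 0.35)) == (42, 49, 49)


@given(st.integers(4, 400))
@settings(deadline=None, max_examples=60)
def test_trial_mix_allocation_property(n):
    go, nogo, catch = trial_type_counts(n)
    assert go + nogo + catch == n
    assert go == int(np.floor(0.30 * n))
    assert nogo == int(np.floor(0.35 * n))


def test_session_trial_counts(task_bundle):
    _, (_, trials, _, _) = task_bundle
    counts = trials["trial_type"].value_counts()
    assert counts["Go"] == 42 and counts["Nogo"] == 49 and counts["catch"] == 49


def test_outcome_counts_sum_to_n_trials(task_bundle):
    _, (_, trials, _, _) = task_bundle
    assert trials["outcome"].notna().all()
    assert len(trials) == 140


def test_same_seed_bit_identical():
    cfg = fast_config(n_cells=8, n_trials=20)
    a = generate_session(cfg, "initial-expert", seed=7)
    b = generate_session(cfg, "initial-expert", seed=7)
    assert np.array_equal(a[0].F, b[0].F)
    assert a[1]["outcome"].tolist() == b[1]["outcome"].tolist()


def test_invalid_config_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(trial_mix=(0.5, 0.2, 0.2)).validate()
    with pytest.raises(ValueError, match="cutoff"):
        SimConfig(frame_rate_hz=8.0).validate()
    with pytest.raises(ValueError, match="below 1"):
        trial_type_counts(2)
    with pytest.raises(ValueError, match="phase"):
        generate_session(fast_config(n_cells=2, n_trials=20), "graduate", seed=0)


def test_ramp_slope_oracle_on_noiseless_kernels():
    """Least-squares slope of the delay-epoch mean trace: positive for every
    planted ramp-up cell, near zero for nonresponsive cells."""
    cfg = fast_config(
        n_cells=20, n_trials=40, delay_coherence=dict(ZERO_COHERENCE),
        class_probs={"ramp-up": 0.5, "nonresponsive": 0.5},
    )
    rec, trials, _, gt = generate_session(cfg, "initial-expert", seed=3,
                                          noiseless=True)
    corrected = rec.F - 0.7 * rec.Fneu
    tens = pp.epoch_and_baseline(corrected, trials["onset_frame"].to_numpy(),
                                 "delay", "pre-delay-150ms",
                                 frame_rate=rec.frame_rate)
    hit = (trials["outcome"] == "Hit").to_numpy()
    mean_trace = tens.values[hit].mean(axis=0)  # cells x frames
    t = np.arange(mean_trace.shape[1]) / rec.frame_rate
    slopes = np.polyfit(t, mean_trace.T, 1)[0]
    up = gt.cell_class_labels == "ramp-up"
    assert (slopes[up] > 0.05).all()
    assert (np.abs(slopes[~up]) < 1e-6).all()


def test_kernel_conserves_event_count():
    """Transients detected by a threshold oracle on noiseless traces equal
    the planted event count."""
    cfg = fast_config(
        n_cells=6, n_trials=24, delay_coherence=dict(ZERO_COHERENCE),
        class_probs={"stable-Go": 0.5, "nonresponsive": 0.5},
        iti_range_s=(6.0, 8.0),
    )
    rec, trials, _, gt = generate_session(cfg, "initial-expert", seed=5,
                                          noiseless=True)
    corrected = rec.F - 0.7 * rec.Fneu
    corrected -= np.median(corrected, axis=1, keepdims=True)
    amp = cfg.effect_sizes["stable-Go"]
    for c in range(cfg.n_cells):
        above = corrected[c] > amp / 2
        n_transients = int(np.sum(np.diff(above.astype(int)) == 1)
                           + (1 if above[0] else 0))
        assert n_transients == gt.events_per_cell[c]


def test_zero_coherence_null_pvc_and_monotonicity():
    """Delay-epoch PVC is ~0 with no planted coherence and grows with it."""
    means = {}
    for coh in (0.0, 0.3, 0.6):
        cfg = fast_config(
            n_cells=40, class_probs={"nonresponsive": 1.0},
            delay_coherence={**ZERO_COHERENCE, "initial-expert": coh},
        )
        rec, trials, _, _ = generate_session(cfg, "initial-expert", seed=21)
        traces = pp.preprocess_session(rec)
        tens = pp.epoch_and_baseline(traces, trials["onset_frame"].to_numpy(),
                                     "delay", "pre-stim-2s")
        hit = (trials["outcome"] == "Hit").to_numpy()
        means[coh] = pv.session_mean_pvc(pv.build_population_vectors(tens, hit))
    assert abs(means[0.0]) < 0.05
    assert means[0.0] < means[0.3] < means[0.6]


# ---------------------------------------------------------------------------
# learning curves
# ---------------------------------------------------------------------------

def test_learning_curve_crossing_near_configured_session():
    cfg = SimConfig(n_sessions=14, expert_crossing_session=10)
    firsts = []
    for seed in range(20):
        lc = generate_learning_curve(cfg, seed)
        firsts.append(int(np.argmax(lc.dprime[:14] > 1.5)))
    assert all(abs(f - 10) <= 2 for f in firsts)


def test_learning_curve_reversal_restarts_below_threshold():
    lc = generate_learning_curve(SimConfig(), seed=0)
    assert lc.deterministic[lc.reversal_start] < 1.5


def test_equal_hit_fa_probability_gives_zero_dprime():
    lc = generate_learning_curve(SimConfig(dprime_noise_sd=0.0), seed=0)
    equal = np.isclose(lc.hit_p, lc.fa_p)
    assert np.allclose(lc.dprime[equal], 0.0)
    # d' identity: Z(hit) - Z(fa) reproduces the series everywhere
    back = stats.norm.ppf(lc.hit_p) - stats.norm.ppf(lc.fa_p)
    assert np.allclose(back, lc.dprime, atol=1e-9)


def test_noiseless_curve_is_deterministic():
    lc = generate_learning_curve(SimConfig(dprime_noise_sd=0.0), seed=9)
    assert np.array_equal(lc.dprime, lc.deterministic)


# ---------------------------------------------------------------------------
# mapping sessions
# ---------------------------------------------------------------------------

def test_mapping_catalog_and_counts():
    catalog = mapping_catalog()
    assert len(catalog) == 29  # 5 tones + 4 gratings + 20 combinations
    cfg = fast_config(n_cells=5)
    _, trials, _ = generate_mapping_session(cfg, seed=1)
    counts = trials["modality"].value_counts()
    assert counts["auditory"] == 40
    assert counts["visual"] == 32
    assert counts["multisensory"] == 160
    # 8 repetitions of every stimulus type
    reps = trials.groupby(["modality", "frequency_khz", "direction"],
                          dropna=False).size()
    assert (reps == 8).all()


def test_supralinear_gain_two_gives_index_two():
    cfg = fast_config(n_cells=5, multisensory_gain=2.0)
    gt = None
    _, _, gt = generate_mapping_session(cfg, seed=2, noiseless=True)
    cell = int(np.flatnonzero(gt.responsive)[0])
    A = tuning_response(gt, cell, "auditory", 2, None)
    V = tuning_response(gt, cell, "visual", None, 1)
    AV = tuning_response(gt, cell, "multisensory", 2, 1)
    rec = multisensory_index(A, V, AV)
    assert rec.exclusion == "none"
    assert rec.index == pytest.approx(2.0)


def test_mapping_seed_reproducibility():
    cfg = fast_config(n_cells=4)
    _, t1, _ = generate_mapping_session(cfg, seed=3)
    _, t2, _ = generate_mapping_session(cfg, seed=3)
    assert t1["modality"].tolist() == t2["modality"].tolist()
    assert t1["frequency_khz"].fillna(-1).tolist() == t2["frequency_khz"].fillna(-1).tolist()


def test_ground_truth_partitions_cells():
    cfg = fast_config(n_cells=97)
    gt = plant_ground_truth(cfg, seed=0)
    assert gt.cell_class_labels.shape == (97,)
    fracs = {c: np.mean(gt.cell_class_labels == c) for c in cfg.class_probs}
    for c, p in cfg.class_probs.items():
        assert abs(fracs[c] - p) < 2 / 97
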