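"""Linear population decoding with circular-permutation chance estimates.

Decoders are linear SVMs trained on stimulus-period population activity
(traces normalized by the 1 s pre-stimulus baseline, down-sampled to 3 Hz,
cells x time bins flattened per trial). Modality decoding balances classes
to the smallest class before a 70/30 split; frequency decoding pools uni-
and multisensory trials (grating direction collapsed) and splits 70/30
directly. Accuracy is averaged over 50 resampled iterations; chance is the
mean accuracy after circularly rotating the concatenated down-sampled time
series by a random offset (coherently across cells) and retraining, which
decouples activity from trial labels while preserving its statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .preprocess import TrialEpochTensor, downsample

logger = logging.getLogger("popact")

DECODER_BASELINE = "pre-stim-1s"
DECODER_HZ = 3.0
TRAIN_FRAC = 0.7
N_ITERATIONS = 50
N_SHUFFLE = 100


@dataclass
class DecoderFeatures:
    """(trials, cells, time bins) at 3 Hz, plus the flattened view."""

    tensor: np.ndarray

    @property
    def X(self) -> np.ndarray:
        t = self.tensor
        return t.reshape(t.shape[0], -1)

    @property
    def n_bins(self) -> int:
        return self.tensor.shape[2]


def build_decoder_features(tensor: TrialEpochTensor, target_hz: float = DECODER_HZ) -> DecoderFeatures:
    """Down-sample a stimulus-window tensor to 3 Hz decoder features."""
    if tensor.baseline != DECODER_BASELINE:
        raise ValueError(
            f"decoder features require baseline '{DECODER_BASELINE}', "
            f"got '{tensor.baseline}'"
        )
    trials, cells, frames = tensor.values.shape
    flat = tensor.values.reshape(trials * cells, frames)
    ds, _, _ = downsample(flat, tensor.frame_rate, target_hz)
    return DecoderFeatures(ds.reshape(trials, cells, -1))


def balanced_split(labels, task: str, train_frac: float = TRAIN_FRAC,
                   seed: int = 0, rng: np.random.Generator | None = None):
    """Train/test trial indices for one iteration.

    Modality task: classes are equalized to the smallest class before the
    split; the per-class test count is floor(smallest * (1 - train_frac)).
    Frequency task: plain stratified-free 70/30 split over all trials.
    """
    labels = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 4:
        raise ValueError("a class has fewer than 4 trials")
    if task == "modality":
        smallest = counts.min()
        n_test = int(np.floor(smallest * (1 - train_frac)))
        n_train = smallest - n_test
        train_ids, test_ids = [], []
        for c in classes:
            ids = rng.permutation(np.flatnonzero(labels == c))[:smallest]
            train_ids.append(ids[:n_train])
            test_ids.append(ids[n_train: n_train + n_test])
        return np.concatenate(train_ids), np.concatenate(test_ids)
    if task == "frequency":
        n = labels.size
        n_train = int(round(n * train_frac))
        perm = rng.permutation(n)
        return perm[:n_train], perm[n_train:]
    raise ValueError(f"unknown task '{task}'")


def _fit_score(X_train, y_train, X_test, y_test, C: float = 1.0) -> float:
    scaler = StandardScaler().fit(X_train)
    clf = LinearSVC(C=C, multi_class="ovr", max_iter=10000)
    clf.fit(scaler.transform(X_train), y_train)
    return float(clf.score(scaler.transform(X_test), y_test))


def train_eval(features: DecoderFeatures, labels, task: str,
               n_iter: int = N_ITERATIONS, seed: int = 0, C: float = 1.0):
    """Mean linear-SVM accuracy over ``n_iter`` resampled 70/30 splits."""
    labels = np.asarray(labels)
    X = features.X
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    for i in range(n_iter):
        tr, te = balanced_split(labels, task, rng=rng)
        accs[i] = _fit_score(X[tr], labels[tr], X[te], labels[te], C=C)
    return float(accs.mean()), accs


def circular_rotate(tensor: np.ndarray, offset: int) -> np.ndarray:
    """Circularly shift the concatenated trial time series by ``offset`` bins.

    The (trials, cells, bins) tensor is viewed per cell as one concatenated
    series of trials * bins samples and rolled by the same offset for every
    cell, so within-trial cross-cell structure is preserved while activity is
    decoupled from the trial labels. ``offset = 0`` is the identity.
    """
    trials, cells, n_bins = tensor.shape
    series = tensor.transpose(1, 0, 2).reshape(cells, trials * n_bins)
    rolled = np.roll(series, int(offset) % (trials * n_bins), axis=1)
    return rolled.reshape(cells, trials, n_bins).transpose(1, 0, 2)


def circular_shuffle_null(features: DecoderFeatures, labels, task: str,
                          n_shuffle: int = N_SHUFFLE, n_iter: int = N_ITERATIONS,
                          seed: int = 0, C: float = 1.0):
    """Chance accuracy from circular-permutation surrogates.

    For each surrogate, the down-sampled time series (concatenated over
    trials) is circularly rotated by a uniform random offset -- coherently
    across cells -- which misaligns activity and trial labels while keeping
    every temporal and cross-cell statistic of the data. Decoders are
    retrained on each surrogate; the mean over surrogates estimates chance.
    Returns (mean chance accuracy, per-shuffle means).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    trials = features.tensor.shape[0]
    total = trials * features.n_bins
    means = np.empty(n_shuffle)
    for s in range(n_shuffle):
        offset = int(rng.integers(1, total))
        rotated = DecoderFeatures(circular_rotate(features.tensor, offset))
        means[s], _ = train_eval(rotated, labels, task, n_iter=n_iter,
                                 seed=int(rng.integers(2**31)), C=C)
    return float(means.mean()), means


def pairwise_session_matrix(session_features: list, session_labels: list,
                            task: str, n_iter: int = N_ITERATIONS, seed: int = 0,
                            C: float = 1.0) -> np.ndarray:
    """Session x session decoding accuracy on tracked-cell-aligned features.

    Entry (a, b): decoder trained on session a, tested on session b; on the
    diagonal the test set is the held-out 30% of the same session. Feature
    spaces must already be aligned (same matched cells, same bin count).
    """
    n = len(session_features)
    shapes = {f.X.shape[1] for f in session_features}
    if len(shapes) != 1:
        raise ValueError("session feature spaces are not aligned")
    rng = np.random.default_rng(seed)
    acc = np.zeros((n, n))
    for a in range(n):
        Xa = session_features[a].X
        ya = np.asarray(session_labels[a])
        for b in range(n):
            Xb = session_features[b].X
            yb = np.asarray(session_labels[b])
            vals = np.empty(n_iter)
            for i in range(n_iter):
                tr, te = balanced_split(ya, task, rng=rng)
                if a == b:
                    vals[i] = _fit_score(Xa[tr], ya[tr], Xa[te], ya[te], C=C)
                else:
                    vals[i] = _fit_score(Xa[tr], ya[tr], Xb, yb, C=C)
            acc[a, b] = vals.mean()
    return acc
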