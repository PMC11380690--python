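"""Functional subgrouping of matched cells.

Trial-averaged traces (stimulus + delay windows) are concatenated across
learning phases per cell, reduced by PCA to the components explaining >= 90%
of the variance, and clustered by k-means under cosine distance (k = 30 by
default, 20 restarts). A reproducible surrogate for a manual merge step then
agglomerates clusters whose centroid traces correlate above a threshold, and
merged clusters receive semantic labels by template matching (delay ramps,
stimulus boxcars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger("popact")


@dataclass
class FeatureLayout:
    """Column layout of a feature matrix: ordered (phase, window, slice)."""

    segments: list  # of (phase_label, window_label, slice)

    def slices(self, window: str):
        return [(ph, sl) for ph, w, sl in self.segments if w == window]


@dataclass
class ClusterModel:
    features: np.ndarray
    layout: FeatureLayout | None
    assignments: np.ndarray
    k: int
    inertia: float
    n_components: int
    merged_map: np.ndarray | None = None      # raw cluster -> merged cluster
    merged_assignments: np.ndarray | None = None
    semantic_labels: dict = field(default_factory=dict)  # merged id -> label

    def centroid_trace(self, cluster: int, merged: bool = False) -> np.ndarray:
        assign = self.merged_assignments if merged else self.assignments
        members = self.features[assign == cluster]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {cluster} is empty")
        return members.mean(axis=0)


def build_features(traces_by_phase, phase_order=None) -> tuple[np.ndarray, FeatureLayout, np.ndarray]:
    """Concatenate per-phase trial-averaged traces along time.

    ``traces_by_phase`` maps phase label -> (cells, t) array; all phases must
    share the cell axis. Cells with any non-finite value (missing phase) are
    dropped with a log line. Returns (features, layout, kept_cell_index).
    """
    if phase_order is None:
        phase_order = list(traces_by_phase)
    mats = [np.asarray(traces_by_phase[ph], dtype=float) for ph in phase_order]
    n_cells = mats[0].shape[0]
    if any(m.shape[0] != n_cells for m in mats):
        raise ValueError("all phases must contain the same cells")
    features = np.hstack(mats)
    keep = np.isfinite(features).all(axis=1)
    if not keep.all():
        logger.info("build_features: dropped %d cells with missing phases",
                    int((~keep).sum()))
    segments, start = [], 0
    for ph, m in zip(phase_order, mats):
        segments.append((ph, "trace", slice(start, start + m.shape[1])))
        start += m.shape[1]
    return features[keep], FeatureLayout(segments), np.flatnonzero(keep)


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def _cosine_kmeans_once(Xn: np.ndarray, k: int, rng: np.random.Generator,
                        max_iter: int = 300, tol: float = 1e-8):
    """One spherical k-means run; distance = 1 - cosine similarity."""
    n = Xn.shape[0]
    # k-means++ style seeding on cosine distance
    centers = np.empty((k, Xn.shape[1]))
    centers[0] = Xn[rng.integers(n)]
    d = 1.0 - Xn @ centers[0]
    for j in range(1, k):
        w = np.clip(d, 0, None)
        probs = w / w.sum() if w.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = Xn[rng.choice(n, p=probs)]
        d = np.minimum(d, 1.0 - Xn @ centers[j])

    assign = np.full(n, -1)
    prev_inertia = np.inf
    for _ in range(max_iter):
        sim = Xn @ centers.T
        assign = sim.argmax(axis=1)
        inertia = float((1.0 - sim[np.arange(n), assign]).sum())
        for j in range(k):
            members = Xn[assign == j]
            if members.shape[0] == 0:
                # re-seed an empty cluster from the farthest point
                far = (1.0 - sim.max(axis=1)).argmax()
                centers[j] = Xn[far]
                continue
            c = members.mean(axis=0)
            nrm = np.linalg.norm(c)
            centers[j] = c / nrm if nrm > 0 else members[0]
        if prev_inertia - inertia < tol:
            break
        prev_inertia = inertia
    sim = Xn @ centers.T
    assign = sim.argmax(axis=1)
    inertia = float((1.0 - sim[np.arange(n), assign]).sum())
    return assign, inertia


def cluster(
    features: np.ndarray,
    k: int = 30,
    seed: int = 0,
    n_restarts: int = 20,
    var_explained: float = 0.90,
    layout: FeatureLayout | None = None,
) -> ClusterModel:
    """PCA (>= ``var_explained`` variance) then cosine k-means, best of restarts."""
    X = np.asarray(features, dtype=float)
    n, t = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    max_comp = min(n - 1, t)
    pca = PCA(n_components=max_comp, random_state=seed)
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_explained) + 1)
    scores = scores[:, :n_comp]

    Xn = _normalize_rows(scores)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        assign, inertia = _cosine_kmeans_once(Xn, k, rng)
        if best is None or inertia < best[1]:
            best = (assign, inertia)
    assign, inertia = best
    return ClusterModel(
        features=X, layout=layout, assignments=assign, k=k,
        inertia=inertia, n_components=n_comp,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def merge_clusters(model: ClusterModel, threshold: float = 0.8,
                   label_templates: dict | None = None,
                   min_template_r: float = 0.5) -> ClusterModel:
    """Average-linkage agglomeration of cluster centroid traces.

    Groups are merged while the maximum Pearson correlation between group
    centroid traces exceeds ``threshold``. Merged clusters are then labeled
    by the best-matching template (if provided) when r >= ``min_template_r``,
    else "other".
    """
    occupied = sorted(set(model.assignments.tolist()))
    groups = [[c] for c in occupied]

    def group_centroid(group):
        mask = np.isin(model.assignments, group)
        return model.features[mask].mean(axis=0)

    while len(groups) > 1:
        cents = [group_centroid(g) for g in groups]
        best_r, best_pair = -np.inf, None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                r = _safe_corr(cents[i], cents[j])
                if r > best_r:
                    best_r, best_pair = r, (i, j)
        if best_r <= threshold:
            break
        i, j = best_pair
        groups[i] = groups[i] + groups[j]
        del groups[j]

    merged_map = np.full(model.k, -1)
    for mid, group in enumerate(groups):
        for c in group:
            merged_map[c] = mid
    merged_assign = merged_map[model.assignments]

    semantic = {}
    if label_templates:
        for mid in range(len(groups)):
            cent = model.features[merged_assign == mid].mean(axis=0)
            best_label, best_r = "other", min_template_r
            for label, tpl in label_templates.items():
                r = _safe_corr(cent, tpl)
                if r >= best_r:
                    best_label, best_r = label, r
            semantic[mid] = best_label
    else:
        semantic = {mid: "other" for mid in range(len(groups))}

    return ClusterModel(
        features=model.features, layout=model.layout,
        assignments=model.assignments, k=model.k, inertia=model.inertia,
        n_components=model.n_components, merged_map=merged_map,
        merged_assignments=merged_assign, semantic_labels=semantic,
    )


def make_templates(n_stim: int, n_delay: int, n_phases: int = 2,
                   kernel: np.ndarray | None = None) -> dict:
    """Semantic templates over a (stim + delay) x n_phases concatenated trace.

    Ramp templates rise (ramp-up) or fall below baseline (ramp-down) across
    the delay segment of every phase; stimulus templates are boxcars on the
    stimulus segment — all phases for "stable", last phase only for
    "enhanced", first phase only for "inhibited" (the response that
    disappears with learning). Passing the calcium ``kernel`` convolves the
    underlying drives so templates carry the indicator's rise and decay tail;
    without it a sustained stimulus response's decay through the delay is
    systematically misread as a delay ramp.
    """
    block = n_stim + n_delay
    total = block * n_phases

    def shaped(drive):
        if kernel is None:
            return drive
        out = np.convolve(drive, kernel)[: drive.size]
        peak = np.abs(out).max()
        return out / peak if peak > 0 else out

    stim_block = shaped(np.concatenate([np.ones(n_stim), np.zeros(n_delay)]))
    ramp_seg = shaped(np.linspace(0, 1, n_delay))
    ramp_block = np.concatenate([np.zeros(n_stim), ramp_seg])

    def blocks(seg, phases):
        out = np.zeros(total)
        for ph in phases:
            out[ph * block: (ph + 1) * block] = seg
        return out

    all_ph = range(n_phases)
    return {
        "ramp-up": blocks(ramp_block, all_ph),
        "ramp-down": blocks(-ramp_block, all_ph),
        "stable": blocks(stim_block, all_ph),
        "enhanced": blocks(stim_block, [n_phases - 1]),
        "inhibited": blocks(stim_block, [0]),
    }


def ramp_cell_ids(model: ClusterModel, cell_ids=None) -> np.ndarray:
    """Ids of cells in merged clusters labeled ramp-up or ramp-down."""
    if model.merged_assignments is None:
        raise ValueError("model has not been merged")
    ramp_clusters = {mid for mid, lab in model.semantic_labels.items()
                     if lab in ("ramp-up", "ramp-down")}
    mask = np.isin(model.merged_assignments, list(ramp_clusters))
    if cell_ids is None:
        cell_ids = np.arange(model.features.shape[0])
    return np.asarray(cell_ids)[mask]
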