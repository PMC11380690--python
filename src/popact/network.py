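"""Weighted co-activity network metrics.

Nodes are cells; the edge weight between two cells is the Pearson
correlation of their concatenated within-epoch time series across trials
(traces baselined per trial to the 2 s pre-stimulus mean). Positive and
negative correlation regimes are analyzed as separate graphs (negative edges
enter with |r| as weight). Three metrics:

* hubness H_i: mean pairwise correlation of node i to all other nodes;
* geodesic length L_ij: Dijkstra shortest path on edge lengths 1/r_ij;
* triad clustering coefficient C_i: Onnela-style weighted triangle closure
  with edge weights max-normalized over the whole adjacency,
  C_i = 1/(k_i (k_i - 1)) * sum_{j,k} (w^_ij w^_ik w^_jk)^(1/3).

Condition contrasts are bootstrap deltas (resampling nodes or pairs) with
percentile 95% confidence intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .preprocess import TrialEpochTensor

logger = logging.getLogger("popact")

GRAPH_BASELINE = "pre-stim-2s"


@dataclass
class CoactivityGraph:
    r: np.ndarray          # full signed correlation matrix, unit diagonal
    weights: np.ndarray    # regime weights, zero diagonal, zeros off-regime
    regime: str            # "positive" | "negative"
    node_ids: np.ndarray

    @property
    def m(self) -> int:
        return self.r.shape[0]


@dataclass
class NetworkDelta:
    metric: str
    baseline_condition: str
    deltas: dict           # condition -> point estimate (cond mean - baseline mean)
    ci: dict               # condition -> (lo, hi)
    boot: dict             # condition -> bootstrap distribution of the delta


def build_graph(
    tensor: TrialEpochTensor,
    trial_mask: np.ndarray | None = None,
    regime: str = "positive",
    node_ids=None,
) -> CoactivityGraph:
    """Co-activity graph from concatenated within-epoch time series.

    Each cell's series is the concatenation of its epoch frames over the
    (filtered) trials; r_ij is the Pearson correlation over the
    concatenation. Zero-variance cells are removed with a log line.
    """
    if tensor.baseline != GRAPH_BASELINE:
        raise ValueError(
            f"co-activity graph requires baseline '{GRAPH_BASELINE}', "
            f"got '{tensor.baseline}'"
        )
    if regime not in ("positive", "negative"):
        raise ValueError("regime must be 'positive' or 'negative'")
    values = tensor.values
    if trial_mask is not None:
        values = values[np.asarray(trial_mask, dtype=bool)]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    # (cells, trials * frames)
    series = values.transpose(1, 0, 2).reshape(values.shape[1], -1)
    if node_ids is None:
        node_ids = np.arange(series.shape[0])
    node_ids = np.asarray(node_ids)
    keep = series.std(axis=1) > 0
    if not keep.all():
        logger.info("build_graph: removed %d zero-variance cells", int((~keep).sum()))
    series, node_ids = series[keep], node_ids[keep]
    if series.shape[0] < 2:
        raise ValueError("fewer than 2 cells with variance")
    r = np.corrcoef(series)
    np.fill_diagonal(r, 1.0)

    w = r.copy()
    np.fill_diagonal(w, 0.0)
    if regime == "positive":
        w[w <= 0] = 0.0
    else:
        w = np.where(w < 0, -w, 0.0)
    return CoactivityGraph(r=r, weights=w, regime=regime, node_ids=node_ids)


def hubness(graph: CoactivityGraph, include_self: bool = False) -> np.ndarray:
    """H_i: mean regime correlation of node i to the other nodes.

    By default the self-correlation is excluded (divide by m - 1); the
    ``include_self`` switch gives the literal sum over all m including the
    unit diagonal.
    """
    m = graph.m
    if m < 2:
        raise ValueError("hubness needs at least 2 nodes")
    row_sum = graph.weights.sum(axis=1)
    if include_self:
        return (row_sum + 1.0) / m
    return row_sum / (m - 1)


def shortest_paths(graph: CoactivityGraph):
    """All-pairs Dijkstra geodesics on edge lengths 1/r_ij.

    Returns ``(L, mean_finite, n_unreachable)``: L is the full matrix with
    inf for unreachable pairs; the mean is over the finite, distinct pairs;
    unreachable pair count is over distinct pairs.
    """
    w = graph.weights
    lengths = np.zeros_like(w)
    edge = w > 0
    lengths[edge] = 1.0 / w[edge]
    L = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(L, 0.0)
    iu = np.triu_indices(graph.m, k=1)
    vals = L[iu]
    finite = np.isfinite(vals)
    n_unreachable = int((~finite).sum())
    if n_unreachable:
        logger.info("shortest_paths: %d unreachable pairs excluded", n_unreachable)
    mean_finite = float(vals[finite].mean()) if finite.any() else np.nan
    return L, mean_finite, n_unreachable


def clustering_coefficient(graph: CoactivityGraph) -> np.ndarray:
    """Weighted triad clustering coefficient per node.

    Weights are normalized by the maximum over the whole adjacency; the sum
    runs over ordered neighbor pairs (j, k), j != k. Nodes with degree <= 1
    get C_i = 0.
    """
    w = graph.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(graph.m)
    what = w / wmax
    k = (what > 0).sum(axis=1)
    cube = np.cbrt(what)
    # (cube^3)_ii counts ordered triangles (j, k) around i
    tri = np.einsum("ij,jk,ki->i", cube, cube, cube)
    denom = k * (k - 1)
    C = np.zeros(graph.m)
    nz = denom > 0
    C[nz] = tri[nz] / denom[nz]
    return C


def network_metrics(graph: CoactivityGraph) -> dict:
    """Summary dict: per-node hubness and C_i, pairwise finite L statistics."""
    H = hubness(graph)
    L, mean_L, n_unreach = shortest_paths(graph)
    C = clustering_coefficient(graph)
    iu = np.triu_indices(graph.m, k=1)
    Lpairs = L[iu]
    return {
        "hubness": H,
        "mean_hubness": float(H.mean()),
        "path_lengths": Lpairs,
        "mean_path_length": mean_L,
        "n_unreachable": n_unreach,
        "clustering": C,
        "mean_clustering": float(C.mean()),
    }


def bootstrap_delta(
    values_by_condition: dict,
    baseline: str,
    metric: str = "metric",
    n_boot: int = 3000,
    seed: int = 0,
    ci_level: float = 95.0,
) -> NetworkDelta:
    """Bootstrap condition-mean deltas against a baseline condition.

    ``values_by_condition`` maps a condition label to per-unit metric values
    (units = nodes for hubness/C_i, pairs for path length, finite values
    only). Units are resampled with replacement independently within each
    condition; the delta is condition mean - baseline mean with a percentile
    CI.
    """
    if baseline not in values_by_condition:
        raise KeyError(f"baseline condition '{baseline}' not present")
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap resamples", stacklevel=2)
    rng = np.random.default_rng(seed)
    base = np.asarray(values_by_condition[baseline], dtype=float)
    lo_q, hi_q = (100 - ci_level) / 2, 100 - (100 - ci_level) / 2

    deltas, cis, boots = {}, {}, {}
    base_boot = base[rng.integers(0, base.size, size=(n_boot, base.size))].mean(axis=1)
    for cond, vals in values_by_condition.items():
        v = np.asarray(vals, dtype=float)
        point = float(v.mean() - base.mean())
        if cond == baseline:
            boot = np.zeros(n_boot)
        else:
            cond_boot = v[rng.integers(0, v.size, size=(n_boot, v.size))].mean(axis=1)
            boot = cond_boot - base_boot
        deltas[cond] = point
        boots[cond] = boot
        cis[cond] = (float(np.percentile(boot, lo_q)), float(np.percentile(boot, hi_q)))
    return NetworkDelta(metric=metric, baseline_condition=baseline,
                        deltas=deltas, ci=cis, boot=boots)


def removal_shuffle(
    tensor: TrialEpochTensor,
    remove_idx,
    trial_mask: np.ndarray | None = None,
    n_shuffles: int = 30,
    seed: int = 0,
    regime: str = "positive",
):
    """Network metrics after targeted cell removal vs random removals.

    Rebuilds the graph without the targeted cells, then ``n_shuffles`` times
    without a random same-size cell subset. Returns
    ``(targeted_metrics, shuffle_metrics_list)`` of :func:`network_metrics`
    dicts.
    """
    remove_idx = np.asarray(remove_idx, dtype=int)
    n_cells = tensor.values.shape[1]
    if remove_idx.size >= n_cells:
        raise ValueError("removal would empty the graph")

    def metrics_without(idx):
        keep = np.setdiff1d(np.arange(n_cells), idx)
        sub = TrialEpochTensor(
            tensor.values[:, keep, :], tensor.window, tensor.baseline,
            tensor.frame_rate, tensor.trial_index,
        )
        return network_metrics(build_graph(sub, trial_mask=trial_mask, regime=regime))

    targeted = metrics_without(remove_idx)
    rng = np.random.default_rng(seed)
    shuffles = [
        metrics_without(rng.choice(n_cells, size=remove_idx.size, replace=False))
        for _ in range(n_shuffles)
    ]
    return targeted, shuffles
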