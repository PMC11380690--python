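"""Weighted co-activity graph metrics and resampling controls."""

import numpy as np
import networkx as nx
import pytest

from popact import network as nw
from popact.preprocess import TrialEpochTensor

FR = 30.0


def _tensor(values, baseline="pre-stim-2s"):
    return TrialEpochTensor(np.asarray(values, dtype=float), "delay", baseline, FR)


def _graph_from_r(r, regime="positive"):
    r = np.asarray(r, dtype=float)
    w = r.copy()
    np.fill_diagonal(w, 0.0)
    if regime == "positive":
        w[w <= 0] = 0.0
    else:
        w = np.where(w < 0, -w, 0.0)
    return nw.CoactivityGraph(r=r, weights=w, regime=regime,
                              node_ids=np.arange(r.shape[0]))


def test_shared_signal_gives_unit_correlations():
    rng = np.random.default_rng(0)
    common = rng.normal(size=(5, 60))  # trials x frames
    values = np.repeat(common[:, None, :], 4, axis=1)  # 4 identical cells
    g = nw.build_graph(_tensor(values))
    off = g.r[np.triu_indices(4, 1)]
    assert np.allclose(off, 1.0)


def test_independent_noise_mean_abs_r_small():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(50, 50, 60))  # 50 trials x 50 cells x 2 s
    g = nw.build_graph(_tensor(values))
    off = np.abs(g.r[np.triu_indices(50, 1)])
    assert off.mean() < 0.05


def test_trial_permutation_leaves_r_unchanged():
    rng = np.random.default_rng(2)
    values = rng.normal(size=(10, 6, 30))
    a = nw.build_graph(_tensor(values)).r
    perm = rng.permutation(10)
    b = nw.build_graph(_tensor(values[perm])).r
    assert np.allclose(a, b, atol=1e-12)


def test_wrong_baseline_rejected():
    with pytest.raises(ValueError, match="pre-stim-2s"):
        nw.build_graph(_tensor(np.zeros((3, 3, 10)), baseline="none"))


# ---------------------------------------------------------------------------
# hubness
# ---------------------------------------------------------------------------

def test_hubness_all_ones():
    g = _graph_from_r(np.ones((4, 4)))
    assert np.allclose(nw.hubness(g), 1.0)


def test_hubness_three_node_example():
    r = np.array([[1.0, 0.5, 0.2],
                  [0.5, 1.0, 0.8],
                  [0.2, 0.8, 1.0]])
    H = nw.hubness(_graph_from_r(r))
    assert H[0] == pytest.approx(0.35)
    assert H[1] == pytest.approx(0.65)
    assert H[2] == pytest.approx(0.50)


def test_hubness_literal_self_term_switch():
    r = np.array([[1.0, 0.5], [0.5, 1.0]])
    g = _graph_from_r(r)
    assert nw.hubness(g)[0] == pytest.approx(0.5)
    assert nw.hubness(g, include_self=True)[0] == pytest.approx(0.75)


def test_hubness_matches_row_mean_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(8, 200))
    r = np.corrcoef(x)
    g = _graph_from_r(r)
    H = nw.hubness(g)
    for i in range(8):
        manual = np.mean([max(r[i, j], 0.0) for j in range(8) if j != i])
        assert H[i] == pytest.approx(manual, abs=1e-12)


# ---------------------------------------------------------------------------
# geodesics
# ---------------------------------------------------------------------------

def test_indirect_path_shorter_than_weak_direct_edge():
    r = np.array([[1.0, 0.25, 1.0],
                  [0.25, 1.0, 1.0],
                  [1.0, 1.0, 1.0]])
    L, mean_L, n_unreach = nw.shortest_paths(_graph_from_r(r))
    assert L[0, 1] == pytest.approx(2.0)  # via node 2, not 1/0.25 = 4
    assert n_unreach == 0


def test_disconnected_components_excluded_with_count():
    r = np.eye(5)
    r[0, 1] = r[1, 0] = 0.5
    r[2, 3] = r[3, 2] = r[2, 4] = r[4, 2] = r[3, 4] = r[4, 3] = 0.5
    L, mean_L, n_unreach = nw.shortest_paths(_graph_from_r(r))
    assert n_unreach == 2 * 3  # product of component sizes
    assert np.isfinite(mean_L)


def _floyd_warshall(lengths):
    n = lengths.shape[0]
    D = lengths.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def test_dijkstra_matches_floyd_warshall_on_random_graphs():
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = rng.integers(3, 9)
        r = np.corrcoef(rng.normal(size=(n, 30)))
        g = _graph_from_r(r)
        L, *_ = nw.shortest_paths(g)
        lengths = np.full((n, n), np.inf)
        np.fill_diagonal(lengths, 0.0)
        pos = g.weights > 0
        lengths[pos] = 1.0 / g.weights[pos]
        assert np.allclose(L, _floyd_warshall(lengths), equal_nan=True)


# ---------------------------------------------------------------------------
# triad clustering coefficient
# ---------------------------------------------------------------------------

def test_complete_uniform_graph_unit_clustering():
    r = np.full((5, 5), 0.6)
    np.fill_diagonal(r, 1.0)
    C = nw.clustering_coefficient(_graph_from_r(r))
    assert np.allclose(C, 1.0)


def test_degree_one_node_zero_clustering():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.5
    C = nw.clustering_coefficient(_graph_from_r(r))
    assert C[0] == 0.0 and C[2] == 0.0


def test_triangle_weighted_example():
    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.9
    r[0, 2] = r[2, 0] = 0.6
    r[1, 2] = r[2, 1] = 0.3
    C = nw.clustering_coefficient(_graph_from_r(r))
    expected = (1.0 * (0.6 / 0.9) * (0.3 / 0.9)) ** (1 / 3)
    assert np.allclose(C, expected)
    assert C[0] == pytest.approx(0.6057, abs=1e-3)


def test_clustering_matches_direct_triple_enumeration():
    rng = np.random.default_rng(5)
    r = np.corrcoef(rng.normal(size=(7, 40)))
    g = _graph_from_r(r)
    C = nw.clustering_coefficient(g)
    what = g.weights / g.weights.max()
    for i in range(7):
        neigh = np.flatnonzero(what[i] > 0)
        k = neigh.size
        if k < 2:
            assert C[i] == 0.0
            continue
        total = sum((what[i, j] * what[i, m] * what[j, m]) ** (1 / 3)
                    for j in neigh for m in neigh if j != m)
        assert C[i] == pytest.approx(total / (k * (k - 1)), abs=1e-12)


def test_uniform_weights_reduce_to_binary_clustering():
    rng = np.random.default_rng(6)
    adj = (rng.random((10, 10)) < 0.5).astype(float)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    r = adj * 0.7
    np.fill_diagonal(r, 1.0)
    C = nw.clustering_coefficient(_graph_from_r(r))
    G = nx.from_numpy_array(adj)
    binary = np.array([nx.clustering(G, i) for i in range(10)])
    assert np.allclose(C, binary, atol=1e-12)


# ---------------------------------------------------------------------------
# bootstrap deltas and removal shuffles
# ---------------------------------------------------------------------------

def test_bootstrap_delta_baseline_vs_itself():
    rng = np.random.default_rng(7)
    vals = rng.normal(0.3, 0.1, 100)
    delta = nw.bootstrap_delta({"naive": vals, "same": vals.copy()},
                               baseline="naive", n_boot=500, seed=0)
    assert delta.deltas["naive"] == 0.0
    lo, hi = delta.ci["same"]
    assert lo <= 0.0 <= hi


def test_bootstrap_detects_planted_shift():
    rng = np.random.default_rng(8)
    base = rng.normal(0.3, 0.05, 150)
    shifted = base + 0.2
    delta = nw.bootstrap_delta({"naive": base, "expert": shifted},
                               baseline="naive", n_boot=2000, seed=1)
    lo, hi = delta.ci["expert"]
    assert lo > 0.0
    assert delta.deltas["expert"] == pytest.approx(0.2, abs=0.02)


def test_bootstrap_seeded_reproducibility():
    rng = np.random.default_rng(9)
    vals = {"a": rng.normal(size=50), "b": rng.normal(size=50)}
    d1 = nw.bootstrap_delta(vals, "a", n_boot=300, seed=4)
    d2 = nw.bootstrap_delta(vals, "a", n_boot=300, seed=4)
    assert d1.ci == d2.ci


def test_bootstrap_warns_on_few_resamples():
    with pytest.warns(UserWarning):
        nw.bootstrap_delta({"a": np.ones(5), "b": np.ones(5)}, "a", n_boot=50)


def test_removal_of_nothing_is_identity():
    rng = np.random.default_rng(10)
    values = rng.normal(size=(8, 12, 30))
    tens = _tensor(values)
    targeted, shuffles = nw.removal_shuffle(tens, np.array([], dtype=int),
                                            n_shuffles=2, seed=0)
    base = nw.network_metrics(nw.build_graph(tens))
    assert targeted["mean_hubness"] == pytest.approx(base["mean_hubness"])
    assert shuffles[0]["mean_hubness"] == pytest.approx(base["mean_hubness"])


def test_random_target_within_shuffle_range():
    rng = np.random.default_rng(11)
    inside = 0
    for seed in range(5):
        values = np.random.default_rng(seed).normal(size=(10, 20, 30))
        target = rng.choice(20, size=5, replace=False)
        targeted, shuffles = nw.removal_shuffle(_tensor(values), target,
                                                n_shuffles=30, seed=seed)
        hs = [s["mean_hubness"] for s in shuffles]
        inside += min(hs) <= targeted["mean_hubness"] <= max(hs)
    assert inside >= 4


def test_targeted_hub_clique_removal_exceeds_shuffles():
    rng = np.random.default_rng(12)
    n_trials, n_cells, n_frames = 10, 30, 40
    values = rng.normal(size=(n_trials, n_cells, n_frames))
    shared = rng.normal(size=(n_trials, n_frames))
    clique = np.arange(8)
    values[:, clique, :] += 3.0 * shared[:, None, :]
    targeted, shuffles = nw.removal_shuffle(_tensor(values), clique,
                                            n_shuffles=30, seed=0)
    drops = [s["mean_hubness"] - targeted["mean_hubness"] for s in shuffles]
    assert targeted["mean_hubness"] < np.percentile(
        [s["mean_hubness"] for s in shuffles], 5)
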