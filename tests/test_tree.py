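"""Principal-tree fitting, attachment, root, pseudotime and layout."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

import branchforge.tree as bt


def _fit(X, **kw):
    kw.setdefault("max_iter", 100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bt.fit_ppt(X, **kw)


def test_y_shape_recovers_three_tips_one_fork(y_points):
    X, _, _ = y_points
    t = _fit(X, n_nodes=30, sigma=0.01, lam=1.0, seed=0)
    assert len(t.tips) == 3
    assert len(t.forks) == 1


def test_line_gives_a_path_with_monotone_node_order():
    rng = np.random.default_rng(0)
    x = np.sort(rng.uniform(0, 1, 200))
    X = np.c_[x, np.zeros(200)] + rng.normal(0, 0.01, (200, 2))
    t = _fit(X, n_nodes=15, sigma=0.01, lam=1.0, seed=0)
    assert len(t.forks) == 0 and len(t.tips) == 2
    t = bt.compute_pseudotime(t, int(t.tips[np.argmin(t.F[t.tips, 0])]))
    order = np.argsort(t.node_pseudotime)
    assert np.all(np.diff(t.F[order, 0]) > -0.05)


def test_same_seed_reproduces_fit(y_points):
    X, _, _ = y_points
    a = _fit(X, n_nodes=20, sigma=0.01, lam=1.0, seed=4)
    b = _fit(X, n_nodes=20, sigma=0.01, lam=1.0, seed=4)
    assert np.array_equal(a.F, b.F)
    assert np.array_equal(a.edges, b.edges)
    assert np.array_equal(a.R, b.R)


def test_responsibilities_sum_to_one(y_points):
    X, _, _ = y_points
    t = _fit(X, n_nodes=25, sigma=0.05, lam=2.0, seed=1)
    assert np.allclose(t.R.sum(axis=1), 1.0, atol=1e-9)


def test_noiseless_tree_recovered_within_kernel_width():
    """On points lying exactly on a Y, fitted nodes stay near the true
    curve (directed Hausdorff from nodes to curve), across seeds."""
    rng = np.random.default_rng(5)
    t = rng.uniform(0, 1, 400)
    arm = rng.integers(0, 3, 400)
    X = np.empty((400, 2))
    X[arm == 0] = np.c_[t[arm == 0], np.zeros((arm == 0).sum())]
    X[arm == 1] = np.c_[1 + t[arm == 1], 0.5 * t[arm == 1]]
    X[arm == 2] = np.c_[1 + t[arm == 2], -0.5 * t[arm == 2]]
    for seed in range(5):
        fit = _fit(X, n_nodes=30, sigma=0.005, lam=0.5, seed=seed)
        d = cdist(fit.F, X).min(axis=1)
        assert d.max() < 0.1


def test_attach_two_paths_gives_one_path():
    a = _fit(np.c_[[0.0, 0.1, 0.9, 1.0], np.zeros(4)], n_nodes=2, sigma=0.01,
             lam=0.1, seed=0, cell_names=pd.Index(["a0", "a1", "a2", "a3"]))
    b = _fit(np.c_[[2.0, 2.1, 2.9, 3.0], np.zeros(4)], n_nodes=2, sigma=0.01,
             lam=0.1, seed=0, cell_names=pd.Index(["b0", "b1", "b2", "b3"]))
    tip_a, tip_b = bt.closest_tips(a, b)
    m = bt.attach_trees(a, b, tip_a, tip_b)
    assert m.n_nodes == 4
    assert len(m.edges) == len(a.edges) + len(b.edges) + 1
    assert len(m.tips) == 2 and len(m.forks) == 0


def test_attach_rejects_non_tips(y_points):
    X, _, _ = y_points
    a = _fit(X[:150], n_nodes=20, sigma=0.01, lam=1.0, seed=0,
             cell_names=pd.Index([f"a{i}" for i in range(150)]))
    b = _fit(X[150:], n_nodes=20, sigma=0.01, lam=1.0, seed=0,
             cell_names=pd.Index([f"b{i}" for i in range(150)]))
    fork = int(a.forks[0])
    with pytest.raises(ValueError):
        bt.attach_trees(a, b, fork, int(b.tips[0]))


def test_root_selection_prefers_early_cells():
    rng = np.random.default_rng(1)
    x = np.sort(rng.uniform(0, 1, 120))
    X = np.c_[x, np.zeros(120)] + rng.normal(0, 0.005, (120, 2))
    t = _fit(X, n_nodes=10, sigma=0.005, lam=0.5, seed=0)
    times = np.where(x < 0.5, 14.5, 22.0)
    root = bt.select_root(t, times)
    assert root == t.tips[np.argmin(t.F[t.tips, 0])]


def test_root_tie_breaks_to_smaller_node_id():
    X = np.c_[np.linspace(0, 1, 50), np.zeros(50)]
    t = _fit(X, n_nodes=6, sigma=0.01, lam=0.1, seed=0)
    root = bt.select_root(t, np.full(50, 3.0))
    assert root == min(t.tips)


def test_pseudotime_root_anchoring_and_monotonicity(y_points):
    X, _, _ = y_points
    t = _fit(X, n_nodes=30, sigma=0.01, lam=1.0, seed=0)
    root = int(t.tips[np.argmin(t.F[t.tips, 0])])
    t = bt.compute_pseudotime(t, root)
    assert t.node_pseudotime[root] == 0
    lengths = t.edge_lengths()
    first_edge = min(
        lengths[frozenset((root, j))] for j in t.adjacency()[root]
    )
    near_root = t.cell_pseudotime[t.R.argmax(axis=1) == root]
    assert (near_root <= first_edge + 1e-9).all()
    # geodesic distance is nondecreasing along every root->tip node path
    adj = t.adjacency()
    for tip in t.tips:
        if tip == root:
            continue
        # walk back from tip to root via decreasing pseudotime
        node, seen = tip, [tip]
        while node != root:
            node = min(adj[node], key=lambda j: t.node_pseudotime[j])
            seen.append(node)
        assert np.all(np.diff(t.node_pseudotime[seen[::-1]]) >= -1e-9)


def test_pipeline_pseudotime_tracks_planted_truth(pipeline_result):
    res = pipeline_result
    truth = res.clean.cell_meta["true_pseudotime"].reindex(res.ptree.cell_names)
    rho = spearmanr(res.ptree.cell_pseudotime, truth).statistic
    assert rho >= 0.9


def test_subset_tree_identity_and_preservation(pipeline_result):
    t = pipeline_result.ptree
    full = bt.subset_tree(t, list(t.segments))
    assert full.n_nodes == t.n_nodes
    pd.testing.assert_series_equal(full.cell_pseudotime, t.cell_pseudotime)
    # root->first-tip path keeps exactly its cells, pseudotime unchanged
    seg_path = []
    sid = min(t.segments, key=lambda s: t.segments[s]["start_pt"])
    seg_path.append(sid)
    children = [s for s in t.segments if t.segments[s]["start"] == t.segments[sid]["end"]]
    while children:
        seg_path.append(children[0])
        children = [
            s for s in t.segments
            if t.segments[s]["start"] == t.segments[seg_path[-1]]["end"]
        ]
    sub = bt.subset_tree(t, seg_path)
    expect = t.cell_segment.isin(seg_path)
    assert set(sub.cell_names) == set(t.cell_names[expect])
    pd.testing.assert_series_equal(
        sub.cell_pseudotime, t.cell_pseudotime[expect.to_numpy()]
    )


def test_subset_tree_rejects_disconnected_selection(pipeline_result):
    t = pipeline_result.ptree
    leaves_segs = [
        s for s in t.segments
        if not any(t.segments[o]["start"] == t.segments[s]["end"] for o in t.segments)
    ]
    if len(leaves_segs) >= 2:
        with pytest.raises(ValueError):
            bt.subset_tree(t, leaves_segs[:2])


def test_dendrogram_lanes_are_disjoint(pipeline_result):
    t = pipeline_result.ptree
    layout = bt.dendrogram_layout(t, crowdedness=0.2, seed=0)
    assert len(layout) == len(t.cell_names)
    seg = t.cell_segment
    # sibling leaf segments occupy disjoint x-intervals
    leaf_segs = [
        s for s in t.segments
        if not any(t.segments[o]["start"] == t.segments[s]["end"] for o in t.segments)
    ]
    spans = {
        s: (layout.loc[(seg == s).to_numpy(), "x"].min(),
            layout.loc[(seg == s).to_numpy(), "x"].max())
        for s in leaf_segs
    }
    items = sorted(spans.values())
    for (lo1, hi1), (lo2, hi2) in zip(items, items[1:]):
        assert hi1 < lo2


def test_fork_branch_labels_partition(pipeline_result):
    t = pipeline_result.ptree
    fork = int(t.forks[0])
    labels = bt.fork_branch_labels(t, fork)
    post = set(labels.dropna().unique()) - {"pre"}
    assert len(post) == 2
    assert (labels == "pre").sum() > 0
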