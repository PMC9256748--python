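"""Principal-tree (SimplePPT) fitting and pseudotime.

A principal tree summarises a cell population by ``n_nodes`` node positions
F joined by a spanning tree E, fitted by alternating three steps: soft
assignment of cells to nodes with a Gaussian kernel of bandwidth ``sigma``
(responsibilities R), re-estimation of E as the minimum spanning tree over
node-node squared distances, and a penalised least-squares update of F that
balances data fidelity against a ``lambda``-weighted graph-Laplacian
smoothness penalty. Pseudotime is geodesic (edge-length) distance from a
root tip selected by lowest aggregated developmental time; cells inherit
the pseudotime of their best-assigned node plus a clamped projection offset
onto an incident edge. Two separately fitted trees can be joined tip-to-tip,
which is how a branch whose cells overlap another fate in expression space
is recovered as its own trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import (
    connected_components,
    dijkstra,
    minimum_spanning_tree,
)
from scipy.sparse.linalg import splu
from scipy.spatial.distance import cdist


@dataclass
class PrincipalTree:
    """Fitted principal tree with (optionally) root, pseudotime and segments."""

    F: np.ndarray                      # node x dim positions
    edges: np.ndarray                  # (n_nodes - 1, 2) node index pairs
    R: np.ndarray                      # cell x node soft assignments (rows sum to 1)
    X: np.ndarray                      # cell x dim coordinates the tree was fitted to
    sigma: float
    lam: float
    cell_names: pd.Index
    converged: bool = True
    root: int | None = None
    node_pseudotime: np.ndarray | None = None
    cell_pseudotime: pd.Series | None = None
    cell_segment: pd.Series | None = None
    segments: dict = field(default_factory=dict)       # sid -> segment info
    edge_segment: dict = field(default_factory=dict)   # frozenset(edge) -> sid

    @property
    def n_nodes(self) -> int:
        return self.F.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    @property
    def tips(self) -> np.ndarray:
        return np.flatnonzero(self.degrees() == 1)

    @property
    def forks(self) -> np.ndarray:
        return np.flatnonzero(self.degrees() >= 3)

    @property
    def leaves(self) -> np.ndarray:
        """Tips other than the root (terminal fates)."""
        tips = self.tips
        return tips if self.root is None else tips[tips != self.root]

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for u, v in self.edges:
            adj[int(u)].append(int(v))
            adj[int(v)].append(int(u))
        for a in adj.values():
            a.sort()
        return adj

    def assigned_nodes(self) -> np.ndarray:
        return np.asarray(self.R.argmax(axis=1))

    def edge_lengths(self) -> dict[frozenset, float]:
        return {
            frozenset((int(u), int(v))): float(np.linalg.norm(self.F[u] - self.F[v]))
            for u, v in self.edges
        }


def _check_spanning_tree(n_nodes: int, edges: np.ndarray) -> None:
    if len(edges) != n_nodes - 1:
        raise ValueError("edges do not form a spanning tree (wrong edge count)")
    A = sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n_nodes, n_nodes)
    )
    if connected_components(A, directed=False)[0] != 1:
        raise ValueError("edges do not form a spanning tree (disconnected)")


def _soft_assign(X: np.ndarray, F: np.ndarray, sigma: float) -> np.ndarray:
    logits = -cdist(X, F, "sqeuclidean") / sigma
    logits -= logits.max(axis=1, keepdims=True)
    R = np.exp(logits)
    R /= R.sum(axis=1, keepdims=True)
    return R


def _mst_edges(F: np.ndarray) -> np.ndarray:
    D = cdist(F, F, "sqeuclidean")
    T = minimum_spanning_tree(sparse.csr_matrix(D))
    coo = T.tocoo()
    e = np.stack([np.minimum(coo.row, coo.col), np.maximum(coo.row, coo.col)], axis=1)
    return e[np.lexsort((e[:, 1], e[:, 0]))]


def fit_ppt(
    X: np.ndarray,
    n_nodes: int = 100,
    sigma: float = 0.1,
    lam: float = 1.0,
    seed: int = 42,
    max_iter: int = 200,
    tol: float = 1e-5,
    cell_names: pd.Index | None = None,
) -> PrincipalTree:
    """Fit a SimplePPT principal tree to cell coordinates.

    Initial node positions are ``n_nodes`` cells sampled without replacement
    under ``seed``; iteration stops when the maximum node displacement falls
    below ``tol`` or after ``max_iter`` sweeps (then a warning is raised and
    ``converged`` is False). Identical seeds yield identical F, E and R.
    """
    X = np.asarray(X, float)
    n, _ = X.shape
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    if n_nodes > n:
        raise ValueError("n_nodes cannot exceed the number of cells")
    if sigma <= 0 or lam <= 0:
        raise ValueError("sigma and lambda must be positive")
    rng = np.random.default_rng(seed)
    F = X[rng.choice(n, n_nodes, replace=False)].copy()
    edges = _mst_edges(F)
    R = _soft_assign(X, F, sigma)
    converged = False
    for _ in range(max_iter):
        R = _soft_assign(X, F, sigma)
        edges = _mst_edges(F)
        d = R.sum(axis=0)
        L = sparse.coo_matrix(
            (
                np.concatenate([-np.ones(len(edges))] * 2),
                (
                    np.concatenate([edges[:, 0], edges[:, 1]]),
                    np.concatenate([edges[:, 1], edges[:, 0]]),
                ),
            ),
            shape=(n_nodes, n_nodes),
        ).tolil()
        deg = -np.asarray(L.sum(axis=1)).ravel()
        A = sparse.diags(d + 1e-12) + lam * (sparse.diags(deg) + L)
        F_new = splu(A.tocsc()).solve(R.T @ X)
        shift = float(np.abs(F_new - F).max())
        F = F_new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn("fit_ppt did not converge within max_iter", stacklevel=2)
    R = _soft_assign(X, F, sigma)
    edges = _mst_edges(F)
    if cell_names is None:
        cell_names = pd.RangeIndex(n)
    return PrincipalTree(
        F=F, edges=edges, R=R, X=X, sigma=sigma, lam=lam,
        cell_names=pd.Index(cell_names), converged=converged,
    )


def attach_trees(
    a: PrincipalTree, b: PrincipalTree, tip_a: int, tip_b: int
) -> PrincipalTree:
    """Join two trees by a new edge between one tip of each.

    Cells keep their soft assignments on the tree they were fitted to and
    zeros on the other; root and pseudotime are left unset on the result.
    """
    if tip_a not in a.tips:
        raise ValueError(f"node {tip_a} is not a tip of the first tree")
    if tip_b not in b.tips:
        raise ValueError(f"node {tip_b} is not a tip of the second tree")
    if a.X.shape[1] != b.X.shape[1]:
        raise ValueError("trees live in spaces of different dimension")
    if len(a.cell_names.intersection(b.cell_names)) > 0:
        raise ValueError("trees share cell names; cells must be disjoint")
    off = a.n_nodes
    edges = np.vstack([a.edges, b.edges + off, [[tip_a, tip_b + off]]])
    R = np.zeros((len(a.cell_names) + len(b.cell_names), off + b.n_nodes))
    R[: len(a.cell_names), :off] = a.R
    R[len(a.cell_names):, off:] = b.R
    t = PrincipalTree(
        F=np.vstack([a.F, b.F]),
        edges=edges,
        R=R,
        X=np.vstack([a.X, b.X]),
        sigma=a.sigma,
        lam=a.lam,
        cell_names=a.cell_names.append(b.cell_names),
    )
    _check_spanning_tree(t.n_nodes, t.edges)
    return t


def closest_tips(a: PrincipalTree, b: PrincipalTree) -> tuple[int, int]:
    """The pair (tip of a, tip of b) at minimal Euclidean distance."""
    ta, tb = a.tips, b.tips
    D = cdist(a.F[ta], b.F[tb])
    i, j = np.unravel_index(np.argmin(D), D.shape)
    return int(ta[i]), int(tb[j])


def attachment_tips(
    a: PrincipalTree, b: PrincipalTree, cell_times_b
) -> tuple[int, int]:
    """Attachment tips joining the secondary tree by its developmentally
    earliest end.

    The secondary tree's entry tip is the one with the lowest aggregated
    developmental time (the same rule as root selection); the main tree
    contributes its spatially nearest tip. This avoids accidentally joining
    through a terminal state when two fates converge in expression space.
    """
    tip_b = select_root(b, cell_times_b)
    ta = a.tips
    d = np.linalg.norm(a.F[ta] - b.F[tip_b], axis=1)
    return int(ta[int(np.argmin(d))]), tip_b


# ---------------------------------------------------------------------------
# segments (maximal unbranched edge paths)
# ---------------------------------------------------------------------------


def _segment_paths(t: PrincipalTree) -> list[list[int]]:
    """Maximal unbranched node paths, delimited by tips and forks."""
    adj = t.adjacency()
    deg = t.degrees()
    boundary = [i for i in range(t.n_nodes) if deg[i] != 2]
    if not boundary:  # degenerate: pure cycle cannot happen in a tree
        boundary = [0]
    segs: list[list[int]] = []
    seen: set[frozenset] = set()
    for s in sorted(boundary):
        for nb in adj[s]:
            first = frozenset((s, nb))
            if first in seen:
                continue
            path = [s, nb]
            seen.add(first)
            while deg[path[-1]] == 2:
                nxt = [x for x in adj[path[-1]] if x != path[-2]][0]
                seen.add(frozenset((path[-1], nxt)))
                path.append(nxt)
            segs.append(path)
    return segs


def select_root(t: PrincipalTree, cell_times) -> int:
    """Tip with the lowest soft-assignment-weighted mean developmental time.

    ``cell_times`` is an array aligned with ``t.cell_names`` (or a Series
    indexed by them) of numeric, ordinal time values. Each tip aggregates
    the cell times weighted by that tip node's responsibility column, so
    only cells in the tip's neighbourhood contribute; tips with negligible
    assigned mass are excluded; ties break to the smallest node id.
    """
    if isinstance(cell_times, pd.Series):
        cell_times = cell_times.reindex(t.cell_names).to_numpy(float)
    cell_times = np.asarray(cell_times, float)
    if np.isnan(cell_times).any():
        raise ValueError("every cell needs a numeric time value")
    best: tuple[float, int] | None = None
    for tip in t.tips:
        w = t.R[:, tip]
        mass = float(w.sum())
        if mass <= 1e-12:
            continue
        agg = float(w @ cell_times / mass)
        key = (agg, int(tip))
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("no tip has assigned cells")
    return best[1]


def compute_pseudotime(t: PrincipalTree, root: int) -> PrincipalTree:
    """Geodesic pseudotime from ``root`` plus cell projections and segments.

    Node pseudotime is the edge-length (Euclidean) geodesic distance from the
    root. Each cell is assigned to its argmax-responsibility node, projected
    onto the incident edge that best fits it (clamped to the edge), and takes
    the interpolated pseudotime of the projection point. Segments (maximal
    unbranched paths) are oriented away from the root and labelled
    ``seg0, seg1, ...`` in order of their start pseudotime.
    """
    if not 0 <= root < t.n_nodes:
        raise ValueError("root must be a node of the tree")
    lengths = t.edge_lengths()
    rows = np.concatenate([t.edges[:, 0], t.edges[:, 1]])
    cols = np.concatenate([t.edges[:, 1], t.edges[:, 0]])
    w = np.array([lengths[frozenset((int(u), int(v)))] for u, v in t.edges])
    G = sparse.csr_matrix(
        (np.concatenate([w, w]), (rows, cols)), shape=(t.n_nodes, t.n_nodes)
    )
    node_pt = dijkstra(G, directed=False, indices=root)

    # orient segments away from the root and label deterministically
    raw = _segment_paths(t)
    oriented = []
    for path in raw:
        if node_pt[path[0]] > node_pt[path[-1]] or (
            node_pt[path[0]] == node_pt[path[-1]] and path[0] > path[-1]
        ):
            path = path[::-1]
        oriented.append(path)
    oriented.sort(key=lambda p: (node_pt[p[0]], node_pt[p[-1]], p[0], p[-1]))
    segments: dict[str, dict] = {}
    edge_segment: dict[frozenset, str] = {}
    for k, path in enumerate(oriented):
        sid = f"seg{k}"
        segments[sid] = {
            "nodes": path,
            "start": int(path[0]),
            "end": int(path[-1]),
            "start_pt": float(node_pt[path[0]]),
            "end_pt": float(node_pt[path[-1]]),
        }
        for u, v in zip(path[:-1], path[1:]):
            edge_segment[frozenset((int(u), int(v)))] = sid

    adj = t.adjacency()
    assigned = t.assigned_nodes()
    cell_pt = np.empty(len(assigned))
    cell_seg = np.empty(len(assigned), dtype=object)
    for i, k in enumerate(assigned):
        x = t.X[i]
        best = None
        for j in adj[int(k)]:
            e = t.F[j] - t.F[k]
            elen2 = float(e @ e)
            s = 0.0 if elen2 == 0 else float(np.clip((x - t.F[k]) @ e / elen2, 0.0, 1.0))
            proj = t.F[k] + s * e
            d2 = float(np.sum((x - proj) ** 2))
            key = (d2, int(j))
            if best is None or key < best[0]:
                best = (key, j, s)
        _, j, s = best  # type: ignore[misc]
        cell_pt[i] = (1 - s) * node_pt[k] + s * node_pt[j]
        cell_seg[i] = edge_segment[frozenset((int(k), int(j)))]
    return replace(
        t,
        root=int(root),
        node_pseudotime=node_pt,
        cell_pseudotime=pd.Series(cell_pt, index=t.cell_names, name="pseudotime"),
        cell_segment=pd.Series(cell_seg, index=t.cell_names, name="segment"),
        segments=segments,
        edge_segment=edge_segment,
    )


def subset_tree(t: PrincipalTree, keep_segments: list[str]) -> PrincipalTree:
    """Restrict the tree to a connected set of segments.

    Nodes, edges and cells outside the kept segments are dropped; pseudotime
    values are preserved, not re-zeroed. The selection must be connected and
    include the segment nearest the root (the root-side entry point).
    """
    if t.cell_segment is None or t.node_pseudotime is None:
        raise ValueError("compute_pseudotime must be run first")
    unknown = [s for s in keep_segments if s not in t.segments]
    if unknown:
        raise ValueError(f"unknown segment id(s): {unknown}")
    keep_nodes = sorted({n for s in keep_segments for n in t.segments[s]["nodes"]})
    node_map = {old: new for new, old in enumerate(keep_nodes)}
    kept_edges = [
        (node_map[int(u)], node_map[int(v)])
        for u, v in t.edges
        if frozenset((int(u), int(v))) in t.edge_segment
        and t.edge_segment[frozenset((int(u), int(v)))] in keep_segments
    ]
    edges = np.asarray(kept_edges, dtype=int)
    A = sparse.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(len(keep_nodes), len(keep_nodes)),
    )
    if connected_components(A, directed=False)[0] != 1:
        raise ValueError("kept segments do not form a connected subtree")
    cmask = t.cell_segment.isin(keep_segments).to_numpy()
    R = t.R[cmask][:, keep_nodes]
    R = R / R.sum(axis=1, keepdims=True)
    node_pt = t.node_pseudotime[keep_nodes]
    new_root = keep_nodes[int(np.argmin(node_pt))]
    segments = {
        s: {**t.segments[s], "nodes": [node_map[n] for n in t.segments[s]["nodes"]],
            "start": node_map[t.segments[s]["start"]],
            "end": node_map[t.segments[s]["end"]]}
        for s in keep_segments
    }
    edge_segment = {
        frozenset((node_map[a], node_map[b])): sid
        for e, sid in t.edge_segment.items()
        if sid in keep_segments
        for a, b in [tuple(e)]
    }
    return replace(
        t,
        F=t.F[keep_nodes],
        edges=edges,
        R=R,
        X=t.X[cmask],
        cell_names=t.cell_names[cmask],
        root=node_map[new_root],
        node_pseudotime=node_pt,
        cell_pseudotime=t.cell_pseudotime[cmask],
        cell_segment=t.cell_segment[cmask],
        segments=segments,
        edge_segment=edge_segment,
    )


def fork_branch_labels(t: PrincipalTree, fork_node: int) -> pd.Series:
    """Label cells around one fork: the two post-fork branches and 'pre'.

    Cells on segments downstream of each of the fork's two child segments
    get that child segment's id; cells of the progenitor state — the
    fork's immediate parent segment — are labelled ``'pre'``; cells
    elsewhere on the tree (upstream of the progenitor or on other sides of
    earlier forks) get None, keeping the analysis local to the bifurcation.
    """
    if t.cell_segment is None:
        raise ValueError("compute_pseudotime must be run first")
    if fork_node not in t.forks:
        raise ValueError(f"node {fork_node} is not a fork")
    kids = [s for s, info in t.segments.items() if info["start"] == fork_node]
    if len(kids) != 2:
        raise ValueError("fork must have exactly two child segments")
    children = _segment_children(t)

    def _desc(s: str) -> set[str]:
        out, stack = set(), [s]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(children[cur])
        return out

    by_end = {info["end"]: s for s, info in t.segments.items()}
    pre = [by_end[fork_node]] if fork_node in by_end else []
    labels = pd.Series([None] * len(t.cell_names), index=t.cell_names, dtype=object)
    labels[t.cell_segment.isin(pre)] = "pre"
    for c in kids:
        labels[t.cell_segment.isin(_desc(c))] = c
    return labels


# ---------------------------------------------------------------------------
# dendrogram layout
# ---------------------------------------------------------------------------


def _segment_children(t: PrincipalTree) -> dict[str, list[str]]:
    children: dict[str, list[str]] = {s: [] for s in t.segments}
    for sid, info in t.segments.items():
        for oid, oinfo in t.segments.items():
            if oid != sid and oinfo["start"] == info["end"]:
                children[sid].append(oid)
    for kids in children.values():
        kids.sort()
    return children


def dendrogram_layout(
    t: PrincipalTree, crowdedness: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Per-cell 2-D dendrogram coordinates: y is pseudotime, x the segment lane.

    Leaf segments get unit-width lanes; each internal segment is centred over
    its children, which are packed left to right by decreasing subtree size.
    Cells jitter uniformly within ``crowdedness`` of their lane width, seeded
    for determinism.
    """
    if t.cell_pseudotime is None:
        raise ValueError("compute_pseudotime must be run first")
    children = _segment_children(t)
    root_seg = min(
        (s for s in t.segments), key=lambda s: (t.segments[s]["start_pt"], s)
    )

    size: dict[str, int] = {}

    def _size(s: str) -> int:
        size[s] = 1 + sum(_size(c) for c in children[s])
        return size[s]

    _size(root_seg)
    center: dict[str, float] = {}
    width: dict[str, float] = {}

    def _place(s: str, left: float) -> float:
        kids = sorted(children[s], key=lambda c: (-size[c], c))
        if not kids:
            width[s] = 1.0
            center[s] = left + 0.5
            return left + 1.0
        x = left
        for c in kids:
            x = _place(c, x)
        width[s] = 1.0
        center[s] = float(np.mean([center[c] for c in kids]))
        return x

    _place(root_seg, 0.0)
    rng = np.random.default_rng(seed)
    seg = t.cell_segment.to_numpy()
    jitter = rng.uniform(-0.5, 0.5, len(seg)) * crowdedness
    x = np.array([center[s] for s in seg]) + jitter
    return pd.DataFrame(
        {"x": x, "y": t.cell_pseudotime.to_numpy()}, index=t.cell_names
    )
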