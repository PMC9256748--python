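"""Affinity graph, diffusion maps and multiscale space.

The principal tree is fitted in a multiscale diffusion space built from an
adaptive-bandwidth Gaussian KNN affinity: each diffusion component is scaled
by lambda/(1-lambda) so that components with slowly decaying eigenvalues
(long diffusion scales) dominate. Graph community detection (Leiden) on the
same affinity provides cluster labels for doublet screening and
ligand-receptor analysis. External batch-corrected coordinate matrices can
be passed straight into :func:`knn_affinity`, so an integrated space from
any alignment tool slots in unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

import igraph as ig
import leidenalg


@dataclass
class DiffusionSpace:
    """Nontrivial diffusion components of the affinity's Markov chain.

    ``multiscale[:, k] = components[:, k] * eigenvalues[k] / (1 - eigenvalues[k])``.
    """

    eigenvalues: np.ndarray          # descending, in (0, 1]
    components: np.ndarray           # cell x n_eigs
    multiscale: np.ndarray           # cell x n_eigs
    affinity: sparse.csr_matrix


def pca_coords(X: np.ndarray, n_comps: int = 30, scale: bool = True) -> np.ndarray:
    """Standard PCA coordinates (optionally on z-scaled features)."""
    X = np.asarray(X, float)
    if scale:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_comps = min(n_comps, min(X.shape) - 1)
    return PCA(n_components=n_comps, svd_solver="full").fit_transform(X)


def knn_affinity(
    X: np.ndarray, n_neighbors: int = 20, metric: str = "euclidean"
) -> sparse.csr_matrix:
    """Adaptive-bandwidth Gaussian kernel over each cell's nearest neighbours.

    The per-cell bandwidth is the distance to the ceil(k/3)-th neighbour;
    duplicate points would give a zero bandwidth, which is floored at machine
    epsilon scale with a warning. The matrix is symmetrized as the mean of
    itself and its transpose, with a zero diagonal.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1, metric=metric).fit(X)
    dist, idx = nn.kneighbors(X)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    kad = int(np.ceil(n_neighbors / 3)) - 1
    sigma = dist[:, kad].copy()
    if np.any(sigma <= 0):
        warnings.warn("zero adaptive bandwidth (duplicate points); flooring", stacklevel=2)
        floor = max(np.finfo(float).eps, 1e-12 * (dist.max() or 1.0))
        sigma = np.maximum(sigma, floor)
    w = np.exp(-(dist**2) / sigma[:, None] ** 2)
    rows = np.repeat(np.arange(n), n_neighbors)
    A = sparse.csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
    A = (A + A.T) * 0.5
    A.setdiag(0.0)
    A.eliminate_zeros()
    return A.tocsr()


def diffusion_maps(
    affinity: sparse.spmatrix, n_eigs: int = 10, alpha: float = 0.0
) -> DiffusionSpace:
    """Eigen-decompose the row-normalised Markov matrix of the affinity.

    With ``alpha`` > 0 the kernel is first density-renormalised
    (w_ij / (d_i d_j)^alpha, the Coifman-Lafon convention; alpha = 1 removes
    sampling-density effects from the recovered geometry). Works through the
    symmetric conjugate D^-1/2 A D^-1/2 so that a standard Hermitian
    eigensolver applies; the trivial unit eigenvector is dropped and the top
    ``n_eigs`` nontrivial components are returned together with the
    lambda/(1-lambda) multiscale coordinates. If the graph is disconnected,
    only the largest component carries nonzero coordinates (with a warning).
    """
    A = sparse.csr_matrix(affinity)
    n = A.shape[0]
    if n_eigs >= n:
        raise ValueError("n_eigs must be smaller than the number of cells")
    ncomp, labels = connected_components(A, directed=False)
    mask = np.ones(n, dtype=bool)
    if ncomp > 1:
        warnings.warn(
            f"affinity graph has {ncomp} components; using the largest", stacklevel=2
        )
        largest = np.bincount(labels).argmax()
        mask = labels == largest
        A = A[mask][:, mask]
    if alpha > 0:
        q = np.asarray(A.sum(axis=1)).ravel()
        q = np.where(q > 0, q, 1.0) ** alpha
        Qi = sparse.diags(1.0 / q)
        A = Qi @ A @ Qi
    d = np.asarray(A.sum(axis=1)).ravel()
    d = np.where(d > 0, d, 1.0)
    Dis = sparse.diags(1.0 / np.sqrt(d))
    S = Dis @ A @ Dis
    S = (S + S.T) * 0.5
    k = min(n_eigs + 1, S.shape[0] - 1)
    vals, vecs = eigsh(S, k=k, which="LA")
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    phi = Dis @ vecs                      # right eigenvectors of the Markov matrix
    vals, phi = vals[1:], phi[:, 1:]      # drop the trivial unit eigenpair
    # deterministic sign: largest-magnitude entry positive
    for j in range(phi.shape[1]):
        i = np.argmax(np.abs(phi[:, j]))
        if phi[i, j] < 0:
            phi[:, j] *= -1
    lam = np.clip(vals, -1.0, 1.0 - 1e-12)
    scale = np.where(lam < 1.0, lam / (1.0 - lam), 0.0)
    comp = np.zeros((n, phi.shape[1]))
    comp[mask] = phi
    return DiffusionSpace(
        eigenvalues=vals,
        components=comp,
        multiscale=comp * scale,
        affinity=sparse.csr_matrix(affinity),
    )


def cluster_graph(
    affinity: sparse.spmatrix, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on the weighted affinity graph.

    Returns contiguous integer labels, deterministic for a given seed.
    """
    A = sparse.coo_matrix(affinity)
    upper = A.row < A.col
    g = ig.Graph(
        n=A.shape[0],
        edges=list(zip(A.row[upper].tolist(), A.col[upper].tolist())),
        edge_attrs={"weight": A.data[upper].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    # relabel so cluster ids are contiguous in order of first appearance
    _, first = np.unique(labels, return_index=True)
    remap = {old: new for new, old in enumerate(labels[np.sort(first)])}
    return np.asarray([remap[x] for x in labels])
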