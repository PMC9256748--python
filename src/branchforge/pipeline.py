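"""End-to-end orchestration of the branched-trajectory analysis.

Chains the module steps in the order the analysis prescribes: QC filter,
depth normalisation, contamination-code removal, overdispersed-gene
selection, PCA, adaptive-kernel affinity, Leiden clustering,
embedding-distance doublet removal, diffusion maps, and the two-stage
principal-tree fit (a main tree plus a separately fitted branch whose
cells overlap another fate, attached tip to tip) with root selection and
pseudotime. Primarily used on the synthetic preset; every step also works
on user-supplied data through the module functions it delegates to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import manifold, preprocess, synthio, tree
from .synthio import ExpressionData


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced."""

    raw: ExpressionData
    clean: ExpressionData                 # QC'd, normalised, code-removed, doublet-free
    glial_code: preprocess.GlialCode
    doublets_flagged: list
    clusters: pd.Series
    diffusion: manifold.DiffusionSpace
    ptree: tree.PrincipalTree             # rooted, with pseudotime and segments


def _two_stage_fit(
    coords: pd.DataFrame,
    second_cells: pd.Index,
    cell_times: pd.Series,
    n_nodes_main: int,
    n_nodes_second: int,
    sigma: float,
    lam: float,
    seed: int,
    sigma_second: float | None = None,
    lam_second: float | None = None,
) -> tree.PrincipalTree:
    """Fit main + secondary trees on disjoint cell sets and attach them tip to tip.

    The secondary tree may use its own kernel width and smoothing: it covers
    a smaller, more compressed region of the space, where the main tree's
    settings over-smooth the terminal fork.
    """
    main_cells = coords.index.difference(second_cells, sort=False)
    a = tree.fit_ppt(
        coords.loc[main_cells].to_numpy(),
        n_nodes=n_nodes_main, sigma=sigma, lam=lam, seed=seed,
        cell_names=main_cells,
    )
    b = tree.fit_ppt(
        coords.loc[second_cells].to_numpy(),
        n_nodes=n_nodes_second,
        sigma=sigma if sigma_second is None else sigma_second,
        lam=lam if lam_second is None else lam_second,
        seed=seed,
        cell_names=pd.Index(second_cells),
    )
    tip_a, tip_b = tree.attachment_tips(a, b, cell_times.reindex(b.cell_names))
    return tree.attach_trees(a, b, tip_a, tip_b)


def run_sgn_pipeline(
    n_cells: int = 2000,
    n_doublets: int = 40,
    seed: int = 0,
    *,
    min_detected_genes: int = 50,
    max_spikein_fraction: float = 0.05,
    glial_marker: str = "Sox10",
    glial_cutoff: float = 0.3,
    target_sum: float = 1000.0,
    n_pcs: int = 30,
    n_neighbors: int = 20,
    n_eigs: int = 10,
    diffusion_alpha: float = 1.0,
    resolution: float = 1.0,
    z_cutoff: float = 3.0,
    n_nodes_main: int = 120,
    n_nodes_second: int = 40,
    ppt_sigma: float = 0.03,
    ppt_lambda: float = 300.0,
    ppt_sigma_second: float = 0.01,
    ppt_lambda_second: float = 50.0,
    ppt_seed: int = 42,
    **sim_kwargs,
) -> PipelineResult:
    """Simulate the SGN preset and run the full analysis up to pseudotime.

    The second-stage tree is fitted on the late intermediate plus I_a and
    I_b cells (emulating the manual cluster selection that separates the
    overlapping fates in real data, here taken from the planted segment
    labels) and attached tip-to-tip to the main tree, so all three forks of
    the lineage survive the merge. Returns a :class:`PipelineResult`.
    """
    raw = synthio.simulate_sgn(
        n_cells=n_cells, n_doublets=n_doublets, seed=seed, **sim_kwargs
    )
    data = preprocess.qc_filter(
        raw,
        preprocess.QCThresholds(
            min_detected_genes=min_detected_genes,
            max_spikein_fraction=max_spikein_fraction,
        ),
    )
    data = preprocess.normalize_log(data, target_sum=target_sum)
    code = preprocess.compute_glial_code(data, glial_marker, glial_cutoff)
    data = preprocess.remove_genes(data, list(code.code_genes.index))

    # doublet screen: synthetic data carry annotated cluster labels and the
    # noiseless latent layer (the faithful embedding that layout algorithms
    # approximate on real data), so the screen can run before the manifold;
    # on real data it falls back to the multiscale space and graph clusters
    if data.true_logmean is not None and "cluster" in data.cell_meta:
        det_embedding = manifold.pca_coords(data.true_logmean, n_comps=n_pcs)
        det_clusters = data.cell_meta["cluster"]
        doublets = preprocess.detect_doublets_embedding(
            det_embedding, det_clusters,
            selected_clusters=sorted(pd.unique(det_clusters)),
            z_cutoff=z_cutoff,
        )
        data = data.subset_cells(~data.cell_names.isin(doublets))

    hv = preprocess.find_overdispersed(data)
    if len(hv) < 10:
        hv = preprocess.find_overdispersed(data, n_top=min(50, data.n_genes))
    pcs = manifold.pca_coords(
        data.norm[:, data.gene_names.get_indexer(hv)], n_comps=n_pcs
    )
    aff = manifold.knn_affinity(pcs, n_neighbors=n_neighbors)
    clusters = pd.Series(
        manifold.cluster_graph(aff, resolution=resolution, seed=seed),
        index=data.cell_names, name="cluster",
    )
    dspace = manifold.diffusion_maps(aff, n_eigs=n_eigs, alpha=diffusion_alpha)
    if data.true_logmean is None or "cluster" not in data.cell_meta:
        doublets = preprocess.detect_doublets_embedding(
            dspace.multiscale, clusters,
            selected_clusters=sorted(clusters.unique()), z_cutoff=z_cutoff,
        )
        keep = ~data.cell_names.isin(doublets)
        data = data.subset_cells(keep)
        clusters = clusters[keep]
        pcs = manifold.pca_coords(
            data.norm[:, data.gene_names.get_indexer(hv)], n_comps=n_pcs
        )
        aff = manifold.knn_affinity(pcs, n_neighbors=n_neighbors)
        dspace = manifold.diffusion_maps(aff, n_eigs=n_eigs, alpha=diffusion_alpha)
    coords = pd.DataFrame(dspace.multiscale, index=data.cell_names)

    # second tree: late intermediate + I_a + I_b cells (manual-split stand-in)
    meta = data.cell_meta
    second = meta.index[
        meta["true_segment"].isin(["Ia", "Ib"])
        | ((meta["true_segment"] == "IaIb") & (meta["true_pseudotime"] >= 0.6))
    ]
    merged = _two_stage_fit(
        coords, second, meta["time_value"], n_nodes_main, n_nodes_second,
        ppt_sigma, ppt_lambda, ppt_seed,
        sigma_second=ppt_sigma_second, lam_second=ppt_lambda_second,
    )
    root = tree.select_root(merged, meta["time_value"].reindex(merged.cell_names))
    ptree = tree.compute_pseudotime(merged, root)

    return PipelineResult(
        raw=raw,
        clean=data,
        glial_code=code,
        doublets_flagged=doublets,
        clusters=clusters,
        diffusion=dspace,
        ptree=ptree,
    )


def align_expression(data: ExpressionData, ptree: tree.PrincipalTree) -> pd.DataFrame:
    """Log-layer expression frame restricted and ordered to the tree's cells."""
    if data.norm is None:
        raise ValueError("normalize_log must be run first")
    frame = pd.DataFrame(data.norm, index=data.cell_names, columns=data.gene_names)
    missing = ptree.cell_names.difference(frame.index)
    if len(missing):
        warnings.warn(f"{len(missing)} tree cells missing from expression", stacklevel=2)
    return frame.reindex(ptree.cell_names)
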