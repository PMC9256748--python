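"""Quality control, normalisation and contamination cleanup.

Implements the upstream cleanup steps of the pipeline: threshold QC on
detected genes and spike-in read fraction, per-cell depth normalisation with
log1p, overdispersed (highly variable) gene selection from the mean-variance
trend, identification and removal of a contamination "code" of genes
correlated with a marker gene (e.g. the glial marker Sox10), and
embedding-distance doublet flagging within clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .synthio import ExpressionData


@dataclass(frozen=True)
class QCThresholds:
    """Strict lower bound on detected genes, strict upper bound on spike-in fraction."""

    min_detected_genes: int = 1000
    max_spikein_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.min_detected_genes < 0:
            raise ValueError("min_detected_genes must be >= 0")
        if not 0.0 <= self.max_spikein_fraction <= 1.0:
            raise ValueError("max_spikein_fraction must lie in [0, 1]")


@dataclass
class GlialCode:
    """Genes whose expression tracks a contamination marker above a cutoff."""

    marker: str
    correlation_cutoff: float
    code_genes: pd.Series  # gene name -> correlation, all > cutoff


def qc_filter(data: ExpressionData, thresholds: QCThresholds) -> ExpressionData:
    """Keep cells with *more than* ``min_detected_genes`` detected genes and
    *less than* ``max_spikein_fraction`` spike-in reads (both strict)."""
    nd = data.cell_meta["n_detected_genes"].to_numpy()
    sf = data.cell_meta["spikein_fraction"].to_numpy(float)
    keep = (nd > thresholds.min_detected_genes) & (sf < thresholds.max_spikein_fraction)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return data.subset_cells(keep)


def normalize_log(data: ExpressionData, target_sum: float = 1000.0) -> ExpressionData:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Cells with zero total counts are dropped (with a warning) before scaling.
    The raw counts are left untouched; the result lands in ``.norm``.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    tot = data.counts.sum(axis=1)
    if np.any(tot == 0):
        warnings.warn(f"dropping {int((tot == 0).sum())} cells with zero counts",
                      stacklevel=2)
        data = data.subset_cells(tot > 0)
        tot = data.counts.sum(axis=1)
    out = data.copy()
    out.norm = np.log1p(data.counts * (target_sum / tot[:, None]))
    return out


def find_overdispersed(data: ExpressionData, n_top: int | None = None) -> list[str]:
    """Rank genes by standardized positive residual from the mean-variance trend.

    A degree-2 polynomial of log variance on log mean is fitted across genes
    on the log-normalised layer; genes are ranked by residual divided by the
    residual scale. With ``n_top`` None, all genes with positive residual are
    returned.
    """
    if data.norm is None:
        raise ValueError("normalize_log must be run first")
    if data.n_cells < 2:
        raise ValueError("need at least 2 cells")
    mean = data.norm.mean(axis=0)
    var = data.norm.var(axis=0, ddof=1)
    ok = (mean > 0) & (var > 0)
    lm, lv = np.log(mean[ok]), np.log(var[ok])
    if ok.sum() >= 3:
        coef = np.polyfit(lm, lv, deg=min(2, ok.sum() - 1))
        resid = lv - np.polyval(coef, lm)
    else:
        resid = np.zeros(ok.sum())
    scale = resid.std(ddof=1) if resid.size > 1 and resid.std(ddof=1) > 0 else 1.0
    z = np.full(data.n_genes, -np.inf)
    z[ok] = resid / scale
    order = np.lexsort((np.arange(data.n_genes), -z))  # stable: ties by gene position
    names = data.gene_names.to_numpy()
    if n_top is None:
        return [names[i] for i in order if z[i] > 0]
    if n_top > data.n_genes:
        warnings.warn("n_top exceeds the number of genes; returning all", stacklevel=2)
        n_top = data.n_genes
    return [names[i] for i in order[:n_top]]


def compute_glial_code(
    data: ExpressionData, marker: str, cutoff: float = 0.3
) -> GlialCode:
    """Pearson-correlate every gene with ``marker`` on the log layer.

    Genes with correlation strictly above ``cutoff`` form the code; the
    marker itself correlates 1 with itself and is therefore part of its own
    code (and is removed together with it downstream).
    """
    if data.norm is None:
        raise ValueError("normalize_log must be run first")
    if marker not in data.gene_names:
        raise ValueError(f"marker gene {marker!r} not in dataset")
    if data.n_cells < 3:
        raise ValueError("need at least 3 cells")
    m = data.norm[:, data.gene_names.get_loc(marker)]
    if m.std() == 0:
        raise ValueError("marker has zero variance across cells")
    X = data.norm
    Xc = X - X.mean(axis=0)
    mc = m - m.mean()
    denom = np.sqrt((Xc**2).sum(axis=0)) * np.sqrt((mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ mc / np.where(denom > 0, denom, 1.0), 0.0)
    sel = r > cutoff
    code = pd.Series(r[sel], index=data.gene_names[sel], name="correlation")
    return GlialCode(marker=marker, correlation_cutoff=cutoff, code_genes=code)


def remove_genes(data: ExpressionData, genes: list[str]) -> ExpressionData:
    """Drop the listed genes from counts, norm and gene metadata.

    Cells are untouched and detected-gene counts are *not* recomputed — QC
    runs upstream of cleanup. Unknown names are ignored with a warning.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in data.gene_names]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) to remove not found", stacklevel=2)
    keep = ~data.gene_names.isin(genes)
    nd = data.cell_meta["n_detected_genes"].copy()
    out = ExpressionData(
        counts=data.counts[:, keep],
        cell_meta=data.cell_meta,
        gene_meta=data.gene_meta.loc[keep],
        norm=None if data.norm is None else data.norm[:, keep],
        true_logmean=None if data.true_logmean is None else data.true_logmean[:, keep],
    )
    out.cell_meta["n_detected_genes"] = nd  # preserved from upstream QC
    return out


def detect_doublets_embedding(
    embedding: np.ndarray,
    clusters: np.ndarray | pd.Series,
    selected_clusters: list,
    z_cutoff: float = 3.0,
    cell_names=None,
) -> list:
    """Flag cells far from their cluster mates on an embedding.

    Within each selected cluster, each member's mean pairwise distance to the
    other members is standardized (z-score within the cluster); members with
    z strictly above ``z_cutoff`` are flagged. Clusters with fewer than three
    members, or with zero distance variance, are skipped with a warning.
    """
    embedding = np.asarray(embedding, float)
    if isinstance(clusters, pd.Series):
        if cell_names is None:
            cell_names = clusters.index.to_numpy()
        clusters = clusters.to_numpy()
    else:
        clusters = np.asarray(clusters)
    if cell_names is None:
        cell_names = np.arange(len(clusters))
    cell_names = np.asarray(cell_names)
    flagged: list = []
    for cl in selected_clusters:
        idx = np.flatnonzero(clusters == cl)
        if idx.size < 3:
            warnings.warn(f"cluster {cl!r} has fewer than 3 cells; skipped", stacklevel=2)
            continue
        D = squareform(pdist(embedding[idx]))
        mean_d = D.sum(axis=1) / (idx.size - 1)
        sd = mean_d.std(ddof=0)
        if sd == 0:
            warnings.warn(f"cluster {cl!r} has uniform distances; skipped", stacklevel=2)
            continue
        z = (mean_d - mean_d.mean()) / sd
        flagged.extend(cell_names[idx[z > z_cutoff]].tolist())
    return flagged
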