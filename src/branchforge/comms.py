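"""Gene-set recovery scoring and ligand-receptor permutation tests.

Regulon-style activity is scored per cell as the area under the recovery
curve of a gene set within the top fraction of that cell's
expression-ranked genes, normalised to [0, 1] by the maximal achievable
area (the AUCell convention). Cluster-to-cluster ligand-receptor
interaction scores follow the CellPhoneDB recipe: a partner (possibly a
multi-subunit complex) scores as the *minimum* over subunits of the
subunit's mean expression in the cluster, the pair score is the mean of the
two partner scores, and significance comes from permuting cluster labels
over cells with a one-sided, add-one-smoothed p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. a regulon: a factor plus its targets)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("gene set must be nonempty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene set members must be unique")


@dataclass(frozen=True)
class InteractionPair:
    """A ligand-receptor pair; each partner may be a multi-subunit complex."""

    name: str
    partner_a: tuple[str, ...]
    partner_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.partner_a or not self.partner_b:
            raise ValueError("both partners must be nonempty")


@dataclass
class InteractionScore:
    pair: str
    cluster_a: object
    cluster_b: object
    mean_score: float
    p: float


def score_gene_set(expr, gene_set: GeneSet, top_fraction: float = 0.05) -> pd.Series:
    """Recovery-AUC score of a gene set per cell, in [0, 1].

    Genes are ranked per cell by expression, descending, ties broken by
    stable gene order. The recovery curve counts set members among the top
    ``ceil(top_fraction * n_genes)`` ranks; its area is normalised by the
    area achieved when the members occupy the top ranks. Cells where no set
    member is in the gene universe score 0 (with a warning).
    """
    expr = pd.DataFrame(expr)
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    genes = expr.columns
    members = [g for g in gene_set.members if g in genes]
    if not members:
        warnings.warn(f"gene set {gene_set.name!r} has no genes in the universe",
                      stacklevel=2)
        return pd.Series(0.0, index=expr.index, name=gene_set.name)
    G = len(genes)
    X = int(np.ceil(top_fraction * G))
    member_mask = np.asarray(genes.isin(members))
    E = expr.to_numpy(float)
    # stable descending sort: ranks[i, j] = rank (0-based) of gene j in cell i
    order = np.argsort(-E, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(E.shape[0])[:, None]
    ranks[rows, order] = np.arange(G)[None, :]
    mranks = ranks[:, member_mask]                       # cell x n_members
    contrib = np.maximum(X - 1 - mranks, 0) * (mranks < X)
    s = len(members)
    max_area = np.sum(np.maximum(X - 1 - np.arange(min(s, X)), 0))
    scores = contrib.sum(axis=1) / max_area if max_area > 0 else np.zeros(E.shape[0])
    return pd.Series(scores, index=expr.index, name=gene_set.name)


def score_gene_sets(expr, gene_sets: list[GeneSet], top_fraction: float = 0.05) -> pd.DataFrame:
    """Score many gene sets; returns a cell x set activity matrix."""
    return pd.DataFrame({gs.name: score_gene_set(expr, gs, top_fraction)
                         for gs in gene_sets})


def uniform_rank_expectation(set_size: int, n_genes: int, top_fraction: float = 0.05) -> float:
    """Expected recovery-AUC score of a random set under uniform ranks."""
    X = int(np.ceil(top_fraction * n_genes))
    per_member = sum(max(X - 1 - r, 0) for r in range(n_genes)) / n_genes
    max_area = sum(max(X - 1 - j, 0) for j in range(min(set_size, X)))
    return set_size * per_member / max_area if max_area > 0 else 0.0


# ---------------------------------------------------------------------------
# ligand-receptor permutation scoring
# ---------------------------------------------------------------------------


def lr_permutation_test(
    expr,
    clusters,
    pairs: list[InteractionPair],
    n_perm: int = 999,
    min_expr_fraction: float = 0.10,
    seed: int = 0,
) -> list[InteractionScore]:
    """Permutation test of directed cluster-pair ligand-receptor scores.

    For a pair and a directed cluster pair (a -> b), partner A is evaluated
    in cluster a and partner B in cluster b; each partner scores the minimum
    over its subunits of the subunit's mean (log-normalised) expression in
    the cluster, and the pair's mean_score is the mean of the two partner
    scores. A partner counts as expressed only if every subunit is detected
    (count > 0) in more than ``min_expr_fraction`` of the cluster's cells;
    otherwise the directed score is undefined and skipped. p-values are
    one-sided with add-one smoothing over ``n_perm`` label permutations,
    deterministic under ``seed``. Pairs with no gene present are skipped
    with a warning.
    """
    expr = pd.DataFrame(expr)
    if isinstance(clusters, pd.Series):
        clusters = clusters.reindex(expr.index).to_numpy()
    clusters = np.asarray(clusters)
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    genes = expr.columns
    E = expr.to_numpy(float)
    n = E.shape[0]

    usable: list[InteractionPair] = []
    for p in pairs:
        present = [g for g in (*p.partner_a, *p.partner_b) if g in genes]
        if not present:
            warnings.warn(f"pair {p.name!r} has no gene in the dataset; skipped",
                          stacklevel=2)
            continue
        if any(g not in genes for g in (*p.partner_a, *p.partner_b)):
            # missing subunit: min rule cannot be evaluated
            warnings.warn(f"pair {p.name!r} is missing subunits; skipped",
                          stacklevel=2)
            continue
        usable.append(p)

    # restrict to the genes the pairs use, for fast permutation matmuls
    used_genes = sorted({g for p in usable for g in (*p.partner_a, *p.partner_b)})
    gidx = {g: i for i, g in enumerate(used_genes)}
    Eu = E[:, genes.get_indexer(used_genes)]
    a_idx = [np.array([gidx[g] for g in p.partner_a]) for p in usable]
    b_idx = [np.array([gidx[g] for g in p.partner_b]) for p in usable]

    codes = pd.Categorical(clusters, categories=labels).codes
    K = len(labels)
    sizes = np.bincount(codes, minlength=K).astype(float)
    onehot = np.zeros((K, n))
    onehot[codes, np.arange(n)] = 1.0

    def _means(oh: np.ndarray) -> np.ndarray:  # cluster x gene
        return (oh @ Eu) / sizes[:, None]

    obs_means = _means(onehot)
    det = (onehot @ (Eu > 0)) / sizes[:, None]

    # observed directed scores
    entries: list[tuple[int, int, int]] = []       # (pair index, ca code, cb code)
    obs_vals: list[float] = []
    for pi, p in enumerate(usable):
        a_min = obs_means[:, a_idx[pi]].min(axis=1)
        b_min = obs_means[:, b_idx[pi]].min(axis=1)
        a_det = det[:, a_idx[pi]].min(axis=1)
        b_det = det[:, b_idx[pi]].min(axis=1)
        for ca in range(K):
            for cb in range(K):
                if ca == cb:
                    continue
                if a_det[ca] <= min_expr_fraction or b_det[cb] <= min_expr_fraction:
                    continue
                entries.append((pi, ca, cb))
                obs_vals.append(0.5 * (a_min[ca] + b_min[cb]))
    if not entries:
        return []
    ent = np.asarray(entries)
    obs_arr = np.asarray(obs_vals)
    exceed = np.zeros(len(ent), dtype=int)
    P = len(usable)
    for _ in range(n_perm):
        perm_means = _means(onehot[:, rng.permutation(n)])
        A = np.empty((P, K))
        B = np.empty((P, K))
        for pi in range(P):
            A[pi] = perm_means[:, a_idx[pi]].min(axis=1)
            B[pi] = perm_means[:, b_idx[pi]].min(axis=1)
        null = 0.5 * (A[ent[:, 0], ent[:, 1]] + B[ent[:, 0], ent[:, 2]])
        exceed += null >= obs_arr
    return [
        InteractionScore(
            pair=usable[pi].name,
            cluster_a=labels[ca],
            cluster_b=labels[cb],
            mean_score=float(v),
            p=float((1 + x) / (n_perm + 1)),
        )
        for (pi, ca, cb), v, x in zip(entries, obs_arr, exceed)
    ]


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from a TSV with columns (set_name, gene)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby(df.columns[0], sort=False):
        out.append(GeneSet(name=str(name), members=tuple(grp[df.columns[1]].astype(str))))
    return out


def read_pairs(path) -> list[InteractionPair]:
    """Read interaction pairs from a TSV (pair_name, partner_a, partner_b);
    complex subunits are comma-joined within a partner column."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            InteractionPair(
                name=str(row.iloc[0]),
                partner_a=tuple(str(row.iloc[1]).split(",")),
                partner_b=tuple(str(row.iloc[2]).split(",")),
            )
        )
    return out
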