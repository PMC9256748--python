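"""Bifurcation analysis: branch-specific genes, activation timing, modules.

At each fork the two post-bifurcation branches are compared with the
interaction spline model

    g ~ s(pseudotime) + s(pseudotime):Branch + Branch,

where pre-fork cells are carried in both branch fits (shared-smooth
design). Significant genes are tested for upregulation along the
progenitor-to-terminal path (one-sided OLS slope), assigned to the branch
with the higher mean fitted post-fork expression when the between-branch
difference clears a per-fork cutoff, and timed by splitting the path into
10 pseudotime bins and computing the relative expression rate

    r(b_t) = (f(b_{t+1}) - f(b_{t-1})) / (max f - min f)

on the binned mean fitted trend f; the first interior bin whose rate
exceeds a threshold dates the activation, and genes activating strictly
before the fork form the "early" module (competing fate-choice programs),
the rest the "late" module (fate-biasing programs). Sliding windows of
pseudotime-ordered cells quantify module coordination: intra-module and
inter-module mean local Pearson correlations and their difference, the
module "repulsion".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .trends import P_FLOOR, _ols_rss, bspline_basis, fit_trend


def test_fork(
    expr,
    pseudotime,
    branch,
    df: int = 5,
    fdr_cut: float = 0.1,
    pre_label: str = "pre",
) -> pd.DataFrame:
    """Per-gene F-test of the branch-interaction smooth at one fork.

    ``branch`` labels each cell as one of the two post-fork branches or as
    ``pre_label`` for shared pre-fork (progenitor) cells, which enter both
    branch fits. BH correction runs across genes.
    """
    expr = pd.DataFrame(expr)
    pseudotime = np.asarray(pseudotime, float)
    branch = np.asarray(branch)
    post = sorted(set(branch) - {pre_label})
    if len(post) != 2:
        raise ValueError("branch must contain exactly two post-fork labels")
    for b in post:
        if (branch == b).sum() < df + 2:
            raise ValueError(f"branch {b!r} has fewer than df+2 cells")
    pre = branch == pre_label
    # stack: [pre + branch0] labelled 0, [pre + branch1] labelled 1
    m0 = pre | (branch == post[0])
    m1 = pre | (branch == post[1])
    idx = np.concatenate([np.flatnonzero(m0), np.flatnonzero(m1)])
    lab = np.concatenate([np.zeros(m0.sum()), np.ones(m1.sum())])
    Y = expr.to_numpy(float)[idx]
    t = pseudotime[idx]
    B = bspline_basis(t, df)
    ind = lab[:, None]
    X_full = np.hstack([B, B * ind, ind])
    X_red = np.hstack([B, ind])
    n = len(t)
    _, rss_full, p_full = _ols_rss(X_full, Y)
    _, rss_red, p_red = _ols_rss(X_red, Y)
    dfn, dfd = p_full - p_red, n - p_full
    if dfd <= 0:
        raise ValueError("not enough cells for the requested spline df")
    var = Y.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / dfn) / (rss_full / dfd)
    F = np.where(var > 0, np.maximum(F, 0.0), 0.0)
    p = np.clip(np.where(var > 0, stats.f.sf(F, dfn, dfd), 1.0), P_FLOOR, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"F": F, "p": p, "fdr": fdr}, index=expr.columns)


def test_upregulation(expr_gene, pseudotime, path_cells=None) -> tuple[float, float]:
    """OLS slope of one gene on pseudotime and its one-sided p (slope > 0)."""
    y = np.asarray(expr_gene, float)
    t = np.asarray(pseudotime, float)
    if path_cells is not None:
        path_cells = np.asarray(path_cells)
        y, t = y[path_cells], t[path_cells]
    if len(t) < 3:
        raise ValueError("need at least 3 path cells")
    if t.var() == 0:
        raise ValueError("pseudotime has zero variance on the path")
    tc = t - t.mean()
    slope = float((tc @ (y - y.mean())) / (tc @ tc))
    resid = y - y.mean() - slope * tc
    dof = len(t) - 2
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 / float(tc @ tc))
    if se == 0:
        return slope, 0.0 if slope > 0 else 1.0
    tt = slope / se
    return slope, float(stats.t.sf(tt, dof))


def assign_branch(
    fork_fdr: pd.Series,
    mean_fitted: pd.DataFrame,
    cutoff: float,
    fdr_cut: float = 0.05,
) -> pd.Series:
    """Assign each gene to the branch with higher mean fitted post-fork expression.

    ``mean_fitted`` has one column per post-fork branch. A gene is assigned
    only when its fork fdr < ``fdr_cut`` and the between-branch difference
    strictly exceeds ``cutoff``; otherwise it gets None.
    """
    if mean_fitted.shape[1] != 2:
        raise ValueError("mean_fitted must have exactly two branch columns")
    b0, b1 = mean_fitted.columns
    diff = mean_fitted[b0] - mean_fitted[b1]
    out = pd.Series([None] * len(mean_fitted), index=mean_fitted.index, dtype=object)
    ok = (fork_fdr.reindex(mean_fitted.index) < fdr_cut) & (diff.abs() > cutoff)
    out[ok & (diff > 0)] = b0
    out[ok & (diff < 0)] = b1
    return out


def activation(
    f_bins, rate_threshold: float, bin_pseudotimes
) -> tuple[np.ndarray, int | None, float | None]:
    """Centered-difference activation rate over 10 bins of a fitted trend.

    ``f_bins`` holds the mean fitted expression f(b) in 10 ordered bins and
    ``bin_pseudotimes`` the bins' midpoint pseudotimes. Rates are defined for
    interior bins t = 2..9 (1-based) as
    ``r(b_t) = (f(b_{t+1}) - f(b_{t-1})) / (max f - min f)``; the activation
    bin is the first with rate strictly above ``rate_threshold`` (1-based
    index; None if no bin qualifies), and the activation pseudotime is that
    bin's midpoint.
    """
    f = np.asarray(f_bins, float)
    bt = np.asarray(bin_pseudotimes, float)
    if f.ndim != 1 or len(f) != len(bt):
        raise ValueError("f_bins and bin_pseudotimes must be equal-length vectors")
    span = f.max() - f.min()
    if span <= 0:
        raise ValueError("flat binned trend: activation undefined")
    rates = (f[2:] - f[:-2]) / span          # r(b_t) for t = 2..len-1 (1-based)
    above = np.flatnonzero(rates > rate_threshold)
    if above.size == 0:
        return rates, None, None
    bin_1based = int(above[0]) + 2
    return rates, bin_1based, float(bt[bin_1based - 1])


def split_modules(activation_pseudotime: pd.Series, fork_pseudotime: float) -> pd.Series:
    """Label genes early (activation strictly before the fork) or late.

    Genes without a detected activation get None.
    """
    out = pd.Series([None] * len(activation_pseudotime),
                    index=activation_pseudotime.index, dtype=object)
    has = activation_pseudotime.notna()
    out[has & (activation_pseudotime < fork_pseudotime)] = "early"
    out[has & (activation_pseudotime >= fork_pseudotime)] = "late"
    return out


# ---------------------------------------------------------------------------
# orchestration for one fork
# ---------------------------------------------------------------------------


@dataclass
class ForkResult:
    """Full per-gene bifurcation analysis at one fork."""

    fork_pseudotime: float
    branches: tuple[str, str]
    table: pd.DataFrame        # p, fdr, slope, p_up, assigned_branch, activation_*, module
    f_bins: pd.DataFrame       # gene x 10 binned mean fitted values (assigned genes)
    bin_pseudotimes: dict      # branch -> midpoints of the 10 bins


def analyze_fork(
    expr,
    pseudotime,
    branch,
    fork_pseudotime: float,
    df: int = 5,
    fdr_cut: float = 0.1,
    assign_fdr: float = 0.05,
    cutoff: float = 0.3,
    n_bins: int = 10,
    rate_threshold: float = 0.25,
    pre_label: str = "pre",
) -> ForkResult:
    """Run the full bifurcation pipeline at one fork.

    Tests the branch interaction, fits penalized trends along each
    progenitor-to-terminal path, assigns significant genes to branches,
    estimates activation pseudotimes on the binned trends and splits the
    assigned genes into early/late modules relative to ``fork_pseudotime``.
    """
    expr = pd.DataFrame(expr)
    pseudotime = np.asarray(pseudotime, float)
    branch = np.asarray(branch)
    post = sorted(set(branch) - {pre_label})
    res = test_fork(expr, pseudotime, branch, df=df, fdr_cut=fdr_cut,
                    pre_label=pre_label)
    paths = {b: (branch == pre_label) | (branch == b) for b in post}
    post_masks = {b: branch == b for b in post}

    candidates = res.index[res["fdr"] < max(fdr_cut, assign_fdr)]
    fitted_path: dict[str, pd.DataFrame] = {
        b: pd.DataFrame(index=np.flatnonzero(m), columns=candidates, dtype=float)
        for b, m in paths.items()
    }
    mean_fitted = pd.DataFrame(np.nan, index=res.index, columns=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in candidates:
            y = expr[g].to_numpy(float)
            for b in post:
                m = paths[b]
                fit = fit_trend(y[m], pseudotime[m], np.zeros(m.sum()), df=df)
                fitted_path[b].loc[:, g] = fit["fitted"]
                mean_fitted.loc[g, b] = np.nanmean(fit["fitted"][post_masks[b][m]])

    assigned = assign_branch(res["fdr"], mean_fitted.loc[candidates],
                             cutoff=cutoff, fdr_cut=assign_fdr)
    assigned = assigned.reindex(res.index)

    slope = pd.Series(np.nan, index=res.index)
    p_up = pd.Series(np.nan, index=res.index)
    act_pt = pd.Series(np.nan, index=res.index)
    act_bin = pd.Series(pd.NA, index=res.index, dtype="Int64")
    f_bins_rows = {}
    bin_mid: dict[str, np.ndarray] = {}
    for b in post:
        m = paths[b]
        tpath = pseudotime[m]
        # equal-width bins over the local progenitor-to-terminal window;
        # uniform width keeps the centered-difference rates comparable
        edges_ = np.linspace(tpath.min(), tpath.max(), n_bins + 1)
        bin_mid[b] = 0.5 * (edges_[:-1] + edges_[1:])
        which = np.clip(np.digitize(tpath, edges_[1:-1]), 0, n_bins - 1)
        for g in assigned.index[assigned == b]:
            y = expr[g].to_numpy(float)[m]
            sl, pu = test_upregulation(y, tpath)
            slope[g], p_up[g] = sl, pu
            fit_vals = fitted_path[b][g].to_numpy(float)
            fb = np.array([
                np.nanmean(fit_vals[which == k]) if np.any(which == k) else np.nan
                for k in range(n_bins)
            ])
            # interpolate empty bins from neighbours so Eq. 4 stays defined
            if np.isnan(fb).any():
                ok = ~np.isnan(fb)
                fb = np.interp(np.arange(n_bins), np.flatnonzero(ok), fb[ok])
            f_bins_rows[g] = fb
            if fb.max() > fb.min():
                _, bin1, pt = activation(fb, rate_threshold, bin_mid[b])
                if bin1 is not None:
                    act_bin[g], act_pt[g] = bin1, pt

    module = split_modules(act_pt, fork_pseudotime)
    module[assigned.isna()] = None
    table = res.copy()
    table["slope"] = slope
    table["p_up"] = p_up
    table["assigned_branch"] = assigned
    table["activation_bin"] = act_bin
    table["activation_pseudotime"] = act_pt
    table["module"] = module
    return ForkResult(
        fork_pseudotime=float(fork_pseudotime),
        branches=(post[0], post[1]),
        table=table,
        f_bins=pd.DataFrame(f_bins_rows).T if f_bins_rows else pd.DataFrame(),
        bin_pseudotimes=bin_mid,
    )


# ---------------------------------------------------------------------------
# sliding-window module correlations
# ---------------------------------------------------------------------------


@dataclass
class WindowCorrelation:
    """Local gene-gene correlations of two modules in one window of cells."""

    window: int
    cells: np.ndarray          # positional indices, pseudotime-ordered
    corr: pd.DataFrame         # (module A + module B) x same, local Pearson
    intra_A: float
    intra_B: float
    inter: float
    repulsion: float           # mean(intra_A, intra_B) - inter


def slide_cors(
    expr,
    pseudotime,
    module_a: list[str],
    module_b: list[str],
    window_size: int,
    stride: int | None = None,
) -> list[WindowCorrelation]:
    """Sliding-window local correlations of two disjoint gene modules.

    Cells are ordered by pseudotime; windows of ``window_size`` consecutive
    cells advance by ``stride`` (default half a window; the final window is
    anchored to the end so every cell is covered). Within each window the
    Pearson correlation among module genes is computed; intra/inter means
    run over within- and cross-module pairs, and genes with zero variance in
    a window are excluded from the means with a warning.
    """
    expr = pd.DataFrame(expr)
    module_a, module_b = list(module_a), list(module_b)
    if not module_a or not module_b:
        raise ValueError("both modules must be nonempty")
    if set(module_a) & set(module_b):
        raise ValueError("modules must be disjoint")
    genes = module_a + module_b
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing}")
    n = len(expr)
    if window_size > n:
        raise ValueError("window_size exceeds the number of cells")
    if stride is None:
        stride = max(window_size // 2, 1)
    order = np.argsort(np.asarray(pseudotime, float), kind="stable")
    M = expr[genes].to_numpy(float)[order]
    ia = np.arange(len(module_a))
    ib = np.arange(len(module_a), len(genes))
    starts = list(range(0, n - window_size + 1, stride))
    if starts[-1] != n - window_size:
        starts.append(n - window_size)
    out = []
    for w, s in enumerate(starts):
        W = M[s:s + window_size]
        sd = W.std(axis=0)
        if np.any(sd == 0):
            warnings.warn("zero-variance gene(s) in window; pairs excluded",
                          stacklevel=2)
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(W, rowvar=False)
        np.fill_diagonal(C, 1.0)
        valid = sd > 0

        def _mean_pairs(rows, cols, same: bool) -> float:
            vals = []
            for i in rows:
                for j in cols:
                    if same and j <= i:
                        continue
                    if valid[i] and valid[j]:
                        vals.append(C[i, j])
            return float(np.mean(vals)) if vals else np.nan

        intra_a = _mean_pairs(ia, ia, True)
        intra_b = _mean_pairs(ib, ib, True)
        inter = _mean_pairs(ia, ib, False)
        out.append(
            WindowCorrelation(
                window=w,
                cells=order[s:s + window_size],
                corr=pd.DataFrame(C, index=genes, columns=genes),
                intra_A=intra_a,
                intra_B=intra_b,
                inter=inter,
                repulsion=float(np.mean([intra_a, intra_b]) - inter),
            )
        )
    return out
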