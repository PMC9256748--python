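"""Branch-wise association testing and spline trend fitting.

Association with the tree is tested per gene by comparing a branch-wise
cubic-spline regression of expression on pseudotime (the tree-dependent
model, one spline per segment) against a global-intercept null with an
F-test; Benjamini-Hochberg correction runs across genes and significance
additionally requires the fitted amplitude A = max - min of the trend to
exceed ``A_cut``. Smooth per-segment trends for significant genes come from
penalized cubic regression splines (ridge on second differences of the
coefficients, smoothing chosen by generalized cross-validation). For two
populations sharing one trajectory, the covariate tests fit

    g ~ s(pseudotime) + s(pseudotime):Covariate + Covariate

and test the interaction smooth (amplitude test) and the comparison against
the no-interaction model (trend test). With an unpenalized spline basis the
two F statistics coincide; both routes are computed and reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

P_FLOOR = 1e-300


def bspline_basis(x: np.ndarray, df: int = 5, bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Cubic B-spline design matrix with ``df`` basis functions.

    Internal knots sit at quantiles of ``x`` (or evenly in ``bounds``); for
    df < 4 a polynomial of degree df is used instead (so df = 1 gives the
    classical intercept + slope design). The basis spans constants, so
    models built on it need no extra intercept.
    """
    x = np.asarray(x, float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df < 4:
        return np.vander(x, df + 1, increasing=True)
    lo, hi = bounds if bounds is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    n_internal = df - 4
    if n_internal > 0:
        qs = np.linspace(0, 1, n_internal + 2)[1:-1]
        internal = np.quantile(x, qs)
        internal = np.clip(internal, lo + 1e-9, hi - 1e-9)
        internal = np.maximum.accumulate(internal)
    else:
        internal = np.array([])
    knots = np.concatenate([[lo] * 4, internal, [hi] * 4])
    xx = np.clip(x, lo, hi - 1e-12 * max(1.0, abs(hi)))
    return BSpline.design_matrix(xx, knots, 3).toarray()


def _ols_rss(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least-squares fit of every column of Y on X: fitted values, RSS, rank."""
    Q, Rm = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(Rm)) > np.abs(Rm).max() * 1e-10)) if Rm.size else 0
    fitted = Q @ (Q.T @ Y)
    rss = ((Y - fitted) ** 2).sum(axis=0)
    return fitted, rss, rank


def _segment_design(
    pseudotime: np.ndarray, segment: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray]:
    """Block design with an independent spline basis per segment.

    Returns (design, used_mask); segments with fewer than df + 2 cells are
    dropped from the fit with a warning.
    """
    segs = pd.unique(segment)
    blocks, used = [], np.zeros(len(pseudotime), dtype=bool)
    for s in segs:
        m = segment == s
        if m.sum() < df + 2:
            warnings.warn(f"segment {s!r} has fewer than df+2 cells; dropped",
                          stacklevel=3)
            continue
        used |= m
    kept = [s for s in segs if (segment == s).sum() >= df + 2]
    pt_used = pseudotime[used]
    seg_used = segment[used]
    width = bspline_basis(np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0]), df).shape[1]
    design = np.zeros((int(used.sum()), len(kept) * width))
    for k, s in enumerate(kept):
        m = seg_used == s
        design[m, k * width:(k + 1) * width] = bspline_basis(pt_used[m], df)
    return design, used


def test_association(
    expr,
    pseudotime,
    segment,
    df: int = 5,
    fdr_cut: float = 1e-4,
    A_cut: float = 0.025,
) -> pd.DataFrame:
    """F-test of branch-wise spline trends against a flat (intercept) model.

    ``expr`` is a cell x gene frame/array of log-scale values. The full model
    fits an independent cubic spline of pseudotime within each segment; the
    reduced model is a single global intercept. Genes are significant when
    BH-corrected p < ``fdr_cut`` and the fitted amplitude exceeds ``A_cut``.
    Zero-variance genes get F = 0, p = 1.
    """
    expr = pd.DataFrame(expr)
    Y = expr.to_numpy(float)
    pseudotime = np.asarray(pseudotime, float)
    segment = np.asarray(segment)
    X, used = _segment_design(pseudotime, segment, df)
    Yu = Y[used]
    n = Yu.shape[0]
    fitted, rss1, p1 = _ols_rss(X, Yu)
    mean0 = Yu.mean(axis=0)
    rss0 = ((Yu - mean0) ** 2).sum(axis=0)
    p0 = 1
    dfn, dfd = p1 - p0, n - p1
    if dfd <= 0:
        raise ValueError("not enough cells for the requested spline df")
    var0 = Yu.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / dfn) / (rss1 / dfd)
    F = np.where(var0 > 0, np.maximum(F, 0.0), 0.0)
    pvals = np.where(var0 > 0, stats.f.sf(F, dfn, dfd), 1.0)
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    A = fitted.max(axis=0) - fitted.min(axis=0)
    full_fitted = np.full_like(Y, np.nan)
    full_fitted[used] = fitted
    out = pd.DataFrame(
        {
            "F": F,
            "p": pvals,
            "fdr": fdr,
            "A": A,
            "significant": (fdr < fdr_cut) & (A > A_cut),
        },
        index=expr.columns,
    )
    out.attrs["fitted"] = pd.DataFrame(full_fitted, index=expr.index, columns=expr.columns)
    out.attrs["used_cells"] = used
    return out


# ---------------------------------------------------------------------------
# penalized trend fitting (GAM-style smooth per segment)
# ---------------------------------------------------------------------------


def _pspline_fit(B: np.ndarray, y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Ridge on second differences of spline coefficients; GCV picks lambda."""
    p = B.shape[1]
    if p < 3:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        return B @ coef
    D = np.diff(np.eye(p), 2, axis=0)
    P = D.T @ D
    BtB, Bty = B.T @ B, B.T @ y
    best = (np.inf, None)
    n = len(y)
    for lam in lambdas:
        M = BtB + lam * P
        try:
            coef = np.linalg.solve(M, Bty)
            H_tr = np.trace(np.linalg.solve(M, BtB))
        except np.linalg.LinAlgError:
            continue
        resid = y - B @ coef
        denom = max(n - H_tr, 1e-8)
        gcv = n * float(resid @ resid) / denom**2
        if gcv < best[0]:
            best = (gcv, coef)
    coef = best[1]
    if coef is None:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    return B @ coef


def fit_trend(
    expr_gene,
    pseudotime,
    segment,
    df: int = 5,
    lambdas: np.ndarray | None = None,
) -> dict:
    """Penalized cubic spline trend of one gene, per segment.

    Returns a dict with per-cell ``fitted`` values (NaN for cells on dropped
    segments), the ``normalized`` minmax-scaled trend (all zeros for a flat
    gene), and the amplitude ``A``.
    """
    y = np.asarray(expr_gene, float)
    pseudotime = np.asarray(pseudotime, float)
    segment = np.asarray(segment)
    if lambdas is None:
        lambdas = np.logspace(-4, 4, 17)
    fitted = np.full(len(y), np.nan)
    for s in pd.unique(segment):
        m = segment == s
        if m.sum() < df + 2:
            warnings.warn(f"segment {s!r} has fewer than df+2 cells; dropped",
                          stacklevel=2)
            continue
        B = bspline_basis(pseudotime[m], df)
        fitted[m] = _pspline_fit(B, y[m], lambdas)
    ok = ~np.isnan(fitted)
    A = float(fitted[ok].max() - fitted[ok].min()) if ok.any() else 0.0
    if ok.any() and A <= 1e-9 * max(1.0, float(np.abs(fitted[ok]).max())):
        A = 0.0  # numerically flat trend
    normalized = np.zeros_like(fitted)
    if A > 0:
        normalized[ok] = (fitted[ok] - fitted[ok].min()) / A
    normalized[~ok] = np.nan
    return {"fitted": fitted, "normalized": normalized, "A": A}


def fit_trends(expr, pseudotime, segment, df: int = 5) -> pd.DataFrame:
    """Penalized trends for many genes; returns a cell x gene fitted frame."""
    expr = pd.DataFrame(expr)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for g in expr.columns:
            out[g] = fit_trend(expr[g].to_numpy(), pseudotime, segment, df)["fitted"]
    return pd.DataFrame(out, index=expr.index)


# ---------------------------------------------------------------------------
# covariate tests (two populations sharing one trajectory)
# ---------------------------------------------------------------------------


def test_covariate(
    expr,
    pseudotime,
    covariate,
    df: int = 5,
    fdr_cut: float = 0.1,
) -> pd.DataFrame:
    """Amplitude and trend tests for a 2-level covariate along one trajectory.

    The full design is [s(t), s(t) x 1{cov=B}, 1{cov=B}]; the amplitude test
    is the F-test that all interaction coefficients vanish, the trend test
    the ANOVA comparison of the full model against [s(t), 1{cov=B}]. BH
    correction is applied within each test family; genes are flagged at
    fdr < ``fdr_cut``.
    """
    expr = pd.DataFrame(expr)
    Y = expr.to_numpy(float)
    pseudotime = np.asarray(pseudotime, float)
    covariate = np.asarray(covariate)
    levels = pd.unique(covariate)
    if len(levels) != 2:
        raise ValueError("covariate must have exactly two levels")
    for lv in levels:
        if (covariate == lv).sum() < df + 2:
            raise ValueError(f"covariate level {lv!r} has fewer than df+2 cells")
    B = bspline_basis(pseudotime, df)
    ind = (covariate == levels[1]).astype(float)[:, None]
    X_full = np.hstack([B, B * ind, ind])
    X_red = np.hstack([B, ind])
    n = Y.shape[0]
    _, rss_full, p_full = _ols_rss(X_full, Y)
    _, rss_red, p_red = _ols_rss(X_red, Y)
    dfn, dfd = p_full - p_red, n - p_full
    if dfd <= 0:
        raise ValueError("not enough cells for the requested spline df")
    with np.errstate(divide="ignore", invalid="ignore"):
        # amplitude: Wald F on the interaction block of the full fit
        F_amp = ((rss_red - rss_full) / dfn) / (rss_full / dfd)
        # trend: ANOVA of full vs reduced model (same statistic for OLS)
        F_trend = ((rss_red - rss_full) / dfn) / (rss_full / dfd)
    var = Y.var(axis=0)
    F_amp = np.where(var > 0, np.maximum(F_amp, 0.0), 0.0)
    F_trend = np.where(var > 0, np.maximum(F_trend, 0.0), 0.0)
    p_amp = np.clip(np.where(var > 0, stats.f.sf(F_amp, dfn, dfd), 1.0), P_FLOOR, 1.0)
    p_trend = np.clip(np.where(var > 0, stats.f.sf(F_trend, dfn, dfd), 1.0), P_FLOOR, 1.0)
    fdr_amp = multipletests(p_amp, method="fdr_bh")[1]
    fdr_trend = multipletests(p_trend, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "p_amplitude": p_amp,
            "fdr_amplitude": fdr_amp,
            "amplitude_flag": fdr_amp < fdr_cut,
            "p_trend": p_trend,
            "fdr_trend": fdr_trend,
            "trend_flag": fdr_trend < fdr_cut,
        },
        index=expr.columns,
    )


def exclusive_genes(results: dict[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Genes significant in exactly one of several per-trajectory test results.

    ``results`` maps trajectory name to a :func:`test_association` frame;
    a gene is exclusive to a trajectory if it is significant there and in no
    other trajectory.
    """
    sig = {k: set(df.index[df["significant"]]) for k, df in results.items()}
    out = {}
    for k, s in sig.items():
        others = set().union(*(v for kk, v in sig.items() if kk != k)) if len(sig) > 1 else set()
        out[k] = sorted(s - others)
    return out
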