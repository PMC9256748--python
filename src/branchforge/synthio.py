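"""Synthetic branched-lineage expression data and on-disk formats.

This module generates Smart-seq2-like count matrices with the statistical
structure assumed by the rest of the pipeline: cells sampled along a rooted
binary lineage tree from overlapping developmental time windows, genes
organised into programs (constant, monotone maturation, pre-bifurcation
"early" modules that compete across sibling branches, post-bifurcation
"late" modules with branch-exclusive expression), a contamination code of
genes co-varying with a single marker gene, planted cross-segment doublets,
and per-cell spike-in read fractions.

It also reads and writes the exchange formats used by the command line
interface: a MatrixMarket count matrix with ``cells.txt`` / ``genes.txt``
name files and tab-separated ``cell_meta.tsv`` / ``gene_meta.tsv`` tables.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ConfigurationError(ValueError):
    """A lineage or program specification is internally inconsistent."""


class FormatError(ValueError):
    """An on-disk matrix or metadata file violates the expected format."""


# ---------------------------------------------------------------------------
# lineage specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One unbranched stretch of the lineage tree.

    ``t0``/``t1`` delimit the pseudotime interval [t0, t1) covered by the
    segment, in arbitrary units; a child segment starts where its parent ends.
    """

    id: str
    parent: str | None
    t0: float
    t1: float


@dataclass
class LineageSpec:
    """Rooted binary lineage tree plus overlapping sampling time windows.

    ``time_windows`` maps an (ordinal) time label, e.g. a developmental stage,
    to the pseudotime interval cells collected at that stage are drawn from.
    Windows overlap, emulating the developmental asynchrony of real tissue,
    and must jointly cover [0, max t].
    """

    segments: list[Segment]
    time_windows: list[tuple[str, tuple[float, float]]]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate segment ids")
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1:
            raise ConfigurationError("exactly one parentless (root) segment required")
        by_id = self.by_id
        for s in self.segments:
            if s.t1 <= s.t0:
                raise ConfigurationError(f"segment {s.id}: empty interval")
            if s.parent is not None:
                if s.parent not in by_id:
                    raise ConfigurationError(f"segment {s.id}: unknown parent {s.parent}")
                if abs(by_id[s.parent].t1 - s.t0) > 1e-9:
                    raise ConfigurationError(
                        f"segment {s.id} must start at parent {s.parent} end"
                    )
        for sid, kids in self._children().items():
            if len(kids) > 2:
                raise ConfigurationError(f"fork at {sid} has more than 2 children")
        if not self.time_windows:
            raise ConfigurationError("at least one time window required")
        # windows must jointly cover [0, max t]
        lo = sorted((max(0.0, a), min(self.max_time, b)) for _, (a, b) in self.time_windows)
        cover = lo[0][0]
        if cover > 1e-9:
            raise ConfigurationError("time windows do not cover pseudotime 0")
        reach = lo[0][1]
        for a, b in lo[1:]:
            if a > reach + 1e-9:
                raise ConfigurationError("time windows leave a gap in pseudotime coverage")
            reach = max(reach, b)
        if reach < self.max_time - 1e-9:
            raise ConfigurationError("time windows do not reach the last pseudotime")

    # -- tree helpers -------------------------------------------------------

    @property
    def by_id(self) -> dict[str, Segment]:
        return {s.id: s for s in self.segments}

    def _children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {s.id: [] for s in self.segments}
        for s in self.segments:
            if s.parent is not None:
                out[s.parent].append(s.id)
        for kids in out.values():
            kids.sort()
        return out

    @property
    def root(self) -> Segment:
        return next(s for s in self.segments if s.parent is None)

    @property
    def leaves(self) -> list[str]:
        kids = self._children()
        return sorted(sid for sid, k in kids.items() if not k)

    @property
    def forks(self) -> dict[str, float]:
        """Segments with two children, mapped to the fork pseudotime (their t1)."""
        kids = self._children()
        return {sid: self.by_id[sid].t1 for sid, k in kids.items() if len(k) == 2}

    def children(self, sid: str) -> list[str]:
        return self._children()[sid]

    def path(self, sid: str) -> list[str]:
        """Segment ids from the root down to (and including) ``sid``."""
        by_id = self.by_id
        out = [sid]
        while by_id[out[-1]].parent is not None:
            out.append(by_id[out[-1]].parent)  # type: ignore[arg-type]
        return out[::-1]

    def subtree(self, sid: str) -> set[str]:
        kids = self._children()
        out, stack = set(), [sid]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(kids[cur])
        return out

    @property
    def max_time(self) -> float:
        return max(s.t1 for s in self.segments)


# ---------------------------------------------------------------------------
# gene programs
# ---------------------------------------------------------------------------

_PROGRAM_CLASSES = {"constant", "monotone", "branch-early", "branch-late", "glial-code", "marker"}


@dataclass(frozen=True)
class GeneProgram:
    """Generative program for one gene.

    ``amplitude`` is the max-minus-min of the mean log expression;
    ``activation`` the pseudotime at which a sigmoidal rise is centred
    (branch and monotone classes); ``target`` the branch segment the program
    commits to; ``marker`` names the marker program a glial-code gene tracks.
    """

    name: str
    klass: str
    target: str | None = None
    amplitude: float = 1.0
    activation: float | None = None
    dispersion: float = 0.3
    baseline: float = 0.5
    marker: str | None = None
    direction: int = 1  # monotone only: +1 rises with pseudotime, -1 falls

    def __post_init__(self) -> None:
        if self.klass not in _PROGRAM_CLASSES:
            raise ConfigurationError(f"unknown program class {self.klass!r}")
        if self.amplitude < 0:
            raise ConfigurationError(f"{self.name}: amplitude must be >= 0")
        if self.klass in ("branch-early", "branch-late") and self.target is None:
            raise ConfigurationError(f"{self.name}: branch program needs a target segment")
        if self.klass == "glial-code" and self.marker is None:
            raise ConfigurationError(f"{self.name}: glial-code program needs a marker")

    def validate_against(self, spec: LineageSpec) -> None:
        if self.klass in ("branch-early", "branch-late"):
            if self.target not in spec.by_id:
                raise ConfigurationError(f"{self.name}: unknown target segment {self.target}")
            fork_t = spec.by_id[self.target].t0
            if self.activation is None:
                raise ConfigurationError(f"{self.name}: branch program needs activation time")
            if self.klass == "branch-early" and not self.activation < fork_t:
                raise ConfigurationError(
                    f"{self.name}: early program must activate before its fork"
                )
            if self.klass == "branch-late" and not self.activation > fork_t:
                raise ConfigurationError(
                    f"{self.name}: late program must activate after its fork"
                )


# ---------------------------------------------------------------------------
# expression container
# ---------------------------------------------------------------------------


@dataclass
class ExpressionData:
    """Cell x gene counts with per-cell/per-gene metadata and a log layer.

    ``counts`` are raw non-negative integers; ``norm`` (when present) is the
    per-cell depth-normalised log1p layer produced by
    :func:`branchforge.preprocess.normalize_log`. Metadata tables are indexed
    by cell and gene name respectively; synthetic datasets additionally carry
    ``true_pseudotime``, ``true_segment``, ``is_doublet`` and program labels.
    """

    counts: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    norm: np.ndarray | None = None
    true_logmean: np.ndarray | None = None  # synthetic only: noiseless mean layer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D cell x gene matrix")
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if self.counts.shape != (len(self.cell_meta), len(self.gene_meta)):
            raise FormatError("counts shape does not match metadata")
        if self.norm is not None and self.norm.shape != self.counts.shape:
            raise FormatError("norm layer shape does not match counts")
        self.cell_meta = self.cell_meta.copy()
        self.cell_meta["n_detected_genes"] = (self.counts > 0).sum(axis=1)
        if "spikein_fraction" in self.cell_meta:
            sf = self.cell_meta["spikein_fraction"].to_numpy(float)
            if np.any((sf < 0) | (sf > 1)):
                raise FormatError("spike-in fractions must lie in [0, 1]")

    # -- conveniences -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_names(self) -> pd.Index:
        return self.cell_meta.index

    @property
    def gene_names(self) -> pd.Index:
        return self.gene_meta.index

    def copy(self) -> "ExpressionData":
        return ExpressionData(
            counts=self.counts.copy(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.copy(),
            norm=None if self.norm is None else self.norm.copy(),
            true_logmean=None if self.true_logmean is None else self.true_logmean.copy(),
        )

    def subset_cells(self, mask_or_names) -> "ExpressionData":
        arr = np.asarray(mask_or_names)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.cell_meta.index.get_indexer(arr)
            if (idx < 0).any():
                raise KeyError("unknown cell name(s) in selection")
        return ExpressionData(
            counts=self.counts[idx],
            cell_meta=self.cell_meta.iloc[idx],
            gene_meta=self.gene_meta,
            norm=None if self.norm is None else self.norm[idx],
            true_logmean=None if self.true_logmean is None else self.true_logmean[idx],
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_dataset(
    spec: LineageSpec,
    programs: list[GeneProgram],
    n_cells: int,
    n_doublets: int = 0,
    seed: int = 0,
    *,
    mean_spikein: float = 0.02,
    sigmoid_width: float | None = None,
    bias_strength: float = 0.5,
    bias_window: float | None = None,
    offpath_decay: float | None = None,
    library_sigma: float = 0.2,
    contamination_fraction: float = 0.3,
    min_doublet_separation: float | None = None,
) -> ExpressionData:
    """Draw a synthetic cell x gene count matrix along a lineage tree.

    Cells are placed uniformly within a uniformly chosen time window and
    routed down a uniformly chosen root-to-leaf path. Each gene's mean log
    expression follows its program: a sigmoidal rise of height ``amplitude``
    centred at ``activation`` (width ``sigmoid_width``, default 5 % of tree
    depth) on the root-to-target lineage, with off-lineage cells decaying
    exponentially past the fork. Pre-fork cells carry a latent fate bias that
    feeds competing early programs with opposite signs, so sibling early
    modules are anti-correlated in cells approaching the fork. Counts are
    negative binomial around per-cell library-size-scaled means; glial-code
    genes are noisy linear functions of their marker's contamination latent;
    doublets average the count-scale means of two cells from distinct
    segments. Everything is reproducible from ``seed``.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be at least 10")
    if n_doublets > n_cells:
        raise ValueError("n_doublets cannot exceed n_cells")
    for p in programs:
        p.validate_against(spec)

    rng = np.random.default_rng(seed)
    depth = spec.max_time
    width = 0.05 * depth if sigmoid_width is None else sigmoid_width
    bias_w = 0.15 * depth if bias_window is None else bias_window
    decay = 0.1 * depth if offpath_decay is None else offpath_decay

    # --- sample cells on the tree -----------------------------------------
    by_id = spec.by_id
    leaves = spec.leaves
    win_idx = rng.integers(0, len(spec.time_windows), n_cells)
    t = np.empty(n_cells)
    seg = np.empty(n_cells, dtype=object)
    leaf_of = np.empty(n_cells, dtype=object)
    labels = np.empty(n_cells, dtype=object)
    paths = {lf: spec.path(lf) for lf in leaves}
    for i in range(n_cells):
        label, (a, b) = spec.time_windows[win_idx[i]]
        labels[i] = label
        ti = rng.uniform(max(a, 0.0), min(b, depth))
        ok = [lf for lf in leaves if ti <= by_id[lf].t1 + 1e-12]
        lf = ok[rng.integers(0, len(ok))]
        leaf_of[i] = lf
        t[i] = ti
        for sid in paths[lf]:
            s = by_id[sid]
            if s.t0 - 1e-12 <= ti < s.t1 or (sid == lf and ti >= s.t1 - 1e-12):
                seg[i] = sid
                break

    # latent fate bias per fork, shared by competing early programs
    fork_bias = {f: rng.uniform(-1.0, 1.0, n_cells) for f in spec.forks}

    # contamination latents, one per marker program (level in log units)
    marker_latent: dict[str, np.ndarray] = {}
    for p in programs:
        if p.klass == "marker":
            lvl = np.zeros(n_cells)
            hit = rng.random(n_cells) < contamination_fraction
            lvl[hit] = rng.uniform(0.3, 1.0, hit.sum()) * p.amplitude
            marker_latent[p.name] = lvl

    # --- mean log expression ----------------------------------------------
    G = len(programs)
    M = np.zeros((n_cells, G))
    anc_cache = {sid: set(spec.path(sid)) for sid in by_id}
    sub_cache = {sid: spec.subtree(sid) for sid in by_id}
    seg_arr = seg
    for j, p in enumerate(programs):
        if p.klass == "constant":
            M[:, j] = p.baseline
        elif p.klass == "monotone":
            act = p.activation if p.activation is not None else 0.5 * depth
            M[:, j] = p.baseline + p.amplitude * _sigmoid(p.direction * (t - act) / width)
        elif p.klass in ("branch-early", "branch-late"):
            S = p.target
            assert S is not None and p.activation is not None
            tf = by_id[S].t0
            lineage = anc_cache[S] | sub_cache[S]
            on = np.fromiter((s in lineage for s in seg_arr), bool, n_cells)
            shared = p.amplitude * _sigmoid((t - p.activation) / width)
            plateau = p.amplitude * _sigmoid((tf - p.activation) / width)
            off_val = plateau * np.exp(-np.maximum(t - tf, 0.0) / decay)
            M[:, j] = p.baseline + np.where(on, shared, off_val)
            if p.klass == "branch-early":
                parent = by_id[S].parent
                if parent in fork_bias:
                    sibs = spec.children(parent)
                    sign = 1.0 if S == sibs[0] else -1.0
                    trunk = np.fromiter(
                        (s in anc_cache[S] and s != S for s in seg_arr), bool, n_cells
                    )
                    ramp = np.clip((t - (tf - bias_w)) / bias_w, 0.0, 1.0)
                    M[trunk, j] += (
                        p.amplitude * bias_strength * ramp[trunk]
                        * sign * fork_bias[parent][trunk]
                    )
        elif p.klass == "marker":
            M[:, j] = p.baseline + marker_latent[p.name]
        elif p.klass == "glial-code":
            src = next((q for q in programs if q.name == p.marker), None)
            if src is None or src.klass != "marker":
                raise ConfigurationError(f"{p.name}: marker {p.marker!r} not found")
            M[:, j] = p.baseline + p.amplitude * marker_latent[src.name] / max(
                src.amplitude, 1e-12
            )

    # --- doublets: average count-scale means of two distinct-segment cells.
    # Both parents must be committed: each at least `min_doublet_separation`
    # past the fork where their lineages diverge. Mixtures involving a
    # progenitor and cells of its own lineage are transcriptionally
    # intermediate — indistinguishable from real transition states — and are
    # not what an embedding-outlier screen targets, so they are not planted.
    is_doublet = np.zeros(n_cells, dtype=bool)
    if n_doublets > 0:
        if len(set(seg_arr)) < 2:
            raise ConfigurationError("doublets require at least two distinct segments")
        delta = 0.2 * depth if min_doublet_separation is None else min_doublet_separation
        join_t = {}
        for s1 in by_id:
            for s2 in by_id:
                common = [sid for sid in spec.path(s1) if sid in anc_cache[s2]]
                join_t[(s1, s2)] = by_id[common[-1]].t1
        mu_scale = np.exp(M)

        def _partners(i: int) -> np.ndarray:
            tj = np.array([join_t[(seg_arr[i], s)] for s in seg_arr])
            depth_past_fork = np.minimum(t[i], t) - tj
            return np.flatnonzero((seg_arr != seg_arr[i]) & (depth_past_fork >= delta))

        eligible = np.array([i for i in range(n_cells) if _partners(i).size > 0])
        if eligible.size < n_doublets:
            raise ConfigurationError(
                "not enough committed cells for the requested number of doublets"
            )
        # spread doublets across committed states proportionally to state
        # size (largest-remainder allocation over segment x pseudotime-decile
        # groups): doublet formation is uniform over the plate, so no state
        # should accumulate an excess by sampling fluctuation
        groups: dict[tuple, list[int]] = {}
        for i in eligible:
            groups.setdefault((seg_arr[i], int(t[i] * 10 / depth)), []).append(i)
        keys = sorted(groups)
        sizes = np.array([len(groups[k]) for k in keys], dtype=float)
        quota = n_doublets * sizes / sizes.sum()
        base = np.floor(quota).astype(int)
        rest = n_doublets - base.sum()
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rest]] += 1
        dbl_list: list[int] = []
        for k, q in zip(keys, base):
            take = min(int(q), len(groups[k]))
            if take > 0:
                dbl_list.extend(rng.choice(groups[k], take, replace=False).tolist())
        dbl = np.array(dbl_list[:n_doublets])
        partner_seg = np.full(n_cells, None, dtype=object)
        for i in dbl:
            others = _partners(i)
            jx = others[rng.integers(0, len(others))]
            mu_scale[i] = 0.5 * (mu_scale[i] + mu_scale[jx])
            partner_seg[i] = seg_arr[jx]
        M = np.log(mu_scale)
        is_doublet[dbl] = True

    # --- counts: NB via gamma-Poisson around library-scaled means -----------
    lib = np.exp(rng.normal(0.0, library_sigma, n_cells))
    mu = lib[:, None] * np.exp(M)
    disp = np.array([max(p.dispersion, 0.0) for p in programs])
    counts = np.empty((n_cells, G), dtype=np.int64)
    for j in range(G):
        if disp[j] > 0:
            lam = rng.gamma(1.0 / disp[j], disp[j] * mu[:, j])
        else:
            lam = mu[:, j]
        counts[:, j] = rng.poisson(lam)

    spike = rng.beta(2.0, 2.0 * (1.0 - mean_spikein) / mean_spikein, n_cells)

    ndig = int(np.ceil(np.log10(max(n_cells, 10))))
    cells = pd.Index([f"cell{str(i).zfill(ndig)}" for i in range(n_cells)], name="cell")
    genes = pd.Index([p.name for p in programs], name="gene")
    # planted cluster annotation: segment x pseudotime band, emulating the
    # fine cluster labels a real analysis would carry into doublet screening
    band = np.minimum((t / (0.15 * depth)).astype(int), int(1 / 0.15))
    cluster = np.array([f"{s}_{b}" for s, b in zip(seg_arr, band)], dtype=object)
    cell_meta = pd.DataFrame(
        {
            "time_label": labels,
            "spikein_fraction": spike,
            "is_doublet": is_doublet,
            "cluster": cluster,
            "true_pseudotime": t,
            "true_segment": seg_arr,
            "doublet_partner_segment": partner_seg if n_doublets > 0 else None,
        },
        index=cells,
    )
    gene_meta = pd.DataFrame(
        {
            "program_class": [p.klass for p in programs],
            "target_segment": [p.target for p in programs],
            "activation": [p.activation for p in programs],
        },
        index=genes,
    )
    return ExpressionData(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta,
                          true_logmean=M)


# ---------------------------------------------------------------------------
# the SGN-like preset: 3 ordered bifurcations, 7 segments
# ---------------------------------------------------------------------------

#: ordinal value of each developmental time label, used for root selection
SGN_TIME_VALUES = {
    "E14.5": 14.5,
    "E15.5": 15.5,
    "E16.5": 16.5,
    "E17.5": 17.5,
    "E18.5": 18.5,
    "P3": 22.0,
}


def sgn_preset() -> tuple[LineageSpec, list[GeneProgram]]:
    """Lineage and program set emulating the spiral ganglion neuron tree.

    Seven segments with three ordered binary decisions — unspecialised cells
    split into I_c versus an intermediate pool, which splits into type II
    versus a transient I_a/I_b state, which finally resolves into I_a versus
    I_b — sampled from six overlapping developmental windows (E14.5 to P3).
    Program parameters (counts, amplitudes, activation offsets) are fixed by
    an internal generator so the preset is identical across calls.
    """
    spec = LineageSpec(
        segments=[
            Segment("uns", None, 0.0, 0.25),
            Segment("Ic", "uns", 0.25, 1.0),
            Segment("int", "uns", 0.25, 0.5),
            Segment("II", "int", 0.5, 1.0),
            Segment("IaIb", "int", 0.5, 0.7),
            Segment("Ia", "IaIb", 0.7, 1.0),
            Segment("Ib", "IaIb", 0.7, 1.0),
        ],
        time_windows=[
            ("E14.5", (0.0, 0.30)),
            ("E15.5", (0.10, 0.45)),
            ("E16.5", (0.25, 0.62)),
            ("E17.5", (0.40, 0.80)),
            ("E18.5", (0.50, 0.92)),
            ("P3", (0.62, 1.0)),
        ],
    )
    rng = np.random.default_rng(20220705)
    programs: list[GeneProgram] = []
    for i in range(80):
        programs.append(
            GeneProgram(f"const{i:02d}", "constant", baseline=rng.uniform(0.5, 2.5))
        )
    # maturation dominates the variance of real developmental data: a large
    # cohort of monotone genes with staggered activations spans the time
    # axis, half rising (synaptic maturation) and half falling (loss of the
    # neurogenesis program in unspecialised cells). A third of them turn
    # over within the unspecialised window, where early differentiation is
    # transcriptionally most dynamic.
    for i in range(60):
        act = rng.uniform(0.03, 0.3) if i < 20 else rng.uniform(0.2, 0.9)
        programs.append(
            GeneProgram(
                f"matur{i:02d}",
                "monotone",
                amplitude=rng.uniform(1.0, 2.5),
                activation=act,
                baseline=0.5,
                direction=1 if i % 2 == 0 else -1,
            )
        )
    fork_children = {"uns": ("Ic", "int"), "int": ("II", "IaIb"), "IaIb": ("Ia", "Ib")}
    for fork, kids in fork_children.items():
        tf = spec.by_id[kids[0]].t0
        for child in kids:
            for i in range(8):
                programs.append(
                    GeneProgram(
                        f"early_{child}_{i}",
                        "branch-early",
                        target=child,
                        amplitude=rng.uniform(1.2, 2.2),
                        activation=tf - rng.uniform(0.10, 0.20),
                        baseline=0.5,
                    )
                )
            # staggered activations spanning the branch: differentiation
            # programs unfold sequentially along a trajectory rather than
            # switching at the fork
            # activation offsets exceed the transition width, so early
            # (pre-fork) and late (post-fork) programs are genuinely
            # distinct classes rather than blurring into the fork
            t_end = spec.by_id[child].t1
            for i in range(8):
                programs.append(
                    GeneProgram(
                        f"late_{child}_{i}",
                        "branch-late",
                        target=child,
                        amplitude=rng.uniform(1.5, 2.5),
                        activation=tf + 0.15 + rng.uniform(0.0, 0.55) * (t_end - tf - 0.15),
                        baseline=0.5,
                    )
                )
    programs.append(GeneProgram("Sox10", "marker", amplitude=3.0, baseline=0.3))
    for i in range(20):
        programs.append(
            GeneProgram(
                f"glia{i:02d}",
                "glial-code",
                marker="Sox10",
                amplitude=rng.uniform(1.5, 3.0),
                baseline=0.3,
            )
        )
    return spec, programs


def simulate_sgn(
    n_cells: int = 2000, n_doublets: int = 40, seed: int = 0, **kwargs
) -> ExpressionData:
    """Simulate the SGN preset; see :func:`sgn_preset` and :func:`simulate_dataset`.

    The preset widens the sigmoid transitions to 8 % of tree depth: fate
    resolution in this lineage is gradual, with cells drifting toward a fate
    rather than switching abruptly.
    """
    spec, programs = sgn_preset()
    kwargs.setdefault("sigmoid_width", 0.12)
    kwargs.setdefault("offpath_decay", 0.2)
    kwargs.setdefault("min_doublet_separation", 0.3)
    data = simulate_dataset(spec, programs, n_cells, n_doublets, seed, **kwargs)
    data.cell_meta["time_value"] = data.cell_meta["time_label"].map(SGN_TIME_VALUES)
    return data


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def write_expression(data: ExpressionData, dir: str | os.PathLike) -> None:
    """Write ``counts.mtx`` + name files + metadata TSVs into ``dir``."""
    os.makedirs(dir, exist_ok=True)
    d = os.fspath(dir)
    spio.mmwrite(
        os.path.join(d, "counts.mtx"),
        sparse.coo_matrix(data.counts),
        field="integer",
    )
    with open(os.path.join(d, "cells.txt"), "w") as fh:
        fh.writelines(f"{c}\n" for c in data.cell_names)
    with open(os.path.join(d, "genes.txt"), "w") as fh:
        fh.writelines(f"{g}\n" for g in data.gene_names)
    data.cell_meta.to_csv(os.path.join(d, "cell_meta.tsv"), sep="\t")
    data.gene_meta.to_csv(os.path.join(d, "gene_meta.tsv"), sep="\t")


def _read_names(path: str) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip() != ""]


def read_expression(
    counts_path: str | os.PathLike,
    cellmeta_path: str | os.PathLike,
    genemeta_path: str | os.PathLike,
) -> ExpressionData:
    """Read counts (MTX bundle or dense TSV) plus metadata, aligned by name.

    An MTX file must sit beside ``cells.txt`` and ``genes.txt``; a dense TSV
    carries cell names in the first column and gene names in the header.
    Metadata rows are aligned to the matrix by name, not position.
    """
    counts_path = os.fspath(counts_path)
    if counts_path.endswith(".mtx"):
        d = os.path.dirname(counts_path)
        mat = spio.mmread(counts_path)
        counts = np.asarray(sparse.coo_matrix(mat).todense())
        cells = _read_names(os.path.join(d, "cells.txt"))
        genes = _read_names(os.path.join(d, "genes.txt"))
        if counts.shape != (len(cells), len(genes)):
            raise FormatError("counts.mtx dimensions do not match name files")
        frame = pd.DataFrame(counts, index=pd.Index(cells, name="cell"),
                             columns=pd.Index(genes, name="gene"))
    else:
        frame = pd.read_csv(counts_path, sep="\t", index_col=0)
        frame.index.name = "cell"
        frame.columns.name = "gene"
    if (frame.to_numpy() < 0).any():
        raise FormatError("negative entries in count matrix")
    if not np.allclose(frame.to_numpy(), np.round(frame.to_numpy())):
        raise FormatError("non-integer entries in count matrix")
    cell_meta = pd.read_csv(cellmeta_path, sep="\t", index_col=0)
    gene_meta = pd.read_csv(genemeta_path, sep="\t", index_col=0)
    if set(cell_meta.index) != set(frame.index):
        raise FormatError("cell names in metadata do not match count matrix")
    if set(gene_meta.index) != set(frame.columns):
        raise FormatError("gene names in metadata do not match count matrix")
    cell_meta = cell_meta.reindex(frame.index)
    gene_meta = gene_meta.reindex(frame.columns)
    return ExpressionData(
        counts=frame.to_numpy().astype(np.int64),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )
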