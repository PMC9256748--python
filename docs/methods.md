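# Methods

This note documents the models implemented in branchforge, the defaults
that matter, what the synthetic generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## The analysis problem

A developing neuronal population is profiled by deep single-cell RNA-seq at
several overlapping developmental stages. Cells form a continuum from an
unspecialized pool to discrete fates through ordered binary decisions. The
analysis reconstructs that continuum as a principal tree in a diffusion
manifold, orders cells by pseudotime, and then interrogates the tree
statistically: which genes change along it, which genes distinguish the two
sides of each bifurcation, when each branch program activates, and how the
competing "early" programs of sibling fates are coordinated before the
decision. Upstream of all of this sit three cleanup steps — threshold QC,
removal of a contamination code, and doublet flagging — without which the
manifold and the tests are distorted.

## Synthetic data generator (`synthio`)

The generator is the package's study system. A `LineageSpec` declares a
rooted binary tree of segments with pseudotime intervals (the preset uses 7
segments over t ∈ [0,1]: unspecialized → {I_c | intermediate},
intermediate → {II | I_a/I_b}, I_a/I_b → {I_a | I_b}, forks at t = 0.25,
0.5, 0.7) and a set of overlapping sampling windows labelled by stage
(E14.5 … P3), reflecting the developmental asynchrony of dissected tissue.

Each gene follows a program for its mean log expression:

- constant: baseline only;
- monotone: baseline + A·σ((±(t − a))/w) — maturation genes, half rising
  and half falling, with one third turning over inside the unspecialized
  window where early differentiation is most dynamic;
- branch-early / branch-late: the same sigmoid on the lineage through the
  target branch; off-lineage cells decay exponentially past the fork
  (time constant 0.2) — early programs activate 0.10–0.20 before their
  fork, late programs at least 0.15 after it, staggered along the branch.
  Activation offsets deliberately exceed the transition width (see below)
  so that "early" and "late" are distinct classes rather than a blur
  around the fork;
- marker / glial-code: a contamination latent (30 % of cells, uniform
  level) drives the marker and, linearly, its code genes;
- pre-fork cells carry a per-fork fate-bias latent u ~ U(−1,1) that feeds
  competing early programs with opposite signs and a ramp over the 15 % of
  pseudotime before the fork — this produces the rising co-ordination and
  mutual repulsion of early modules that the bifurcation analysis measures.

Transitions use a sigmoid width of 12 % of tree depth in the preset: fate
resolution in this system is gradual, with cells drifting toward a fate
rather than switching. Counts are negative binomial (gamma–Poisson) around
library-size-scaled means (log-normal library factors, σ = 0.2; dispersion
0.3), appropriate for deep plate-based protocols. Spike-in fractions are
Beta-distributed with mean 2 %.

Doublets average the count-scale means of two cells and are flagged in
metadata. Both parents must be committed — at least 0.3 pseudotime past the
fork where their lineages diverge — and doublet slots are spread across
committed states proportionally to state size. Mixtures of a progenitor
with its own descendants are deliberately not planted: they are
transcriptionally identical to genuine intermediates, so no embedding
screen can (or should) find them. The generator also emits planted cluster
labels (segment × pseudotime band, ~20 clusters) emulating the fine cluster
annotation a real analysis carries, and keeps the noiseless mean layer,
which the pipeline uses as the doublet-screen embedding (a synthetic
stand-in for the force-directed layouts used on real data, which this
package does not implement). What the generator does **not** emulate: batch effects between
stages (alignment tools exist for real data and the interface accepts any
corrected coordinate matrix), read-level noise, gene–gene regulatory
correlations beyond the module structure, and doublets between similar
cells.

## Cleanup

QC keeps cells with strictly more than `min_detected_genes` detected genes
and strictly less than `max_spikein_fraction` spike-in reads (defaults
1000 and 5 %; the synthetic preset, with ~250 genes, uses 50). Cells are
then depth-normalised to 1,000 counts and log1p-transformed. The
contamination code is every gene whose log-layer Pearson correlation with
the marker exceeds 0.3; the marker is removed together with its code — a
contaminant signature should not survive its own removal. Doublet flagging
standardises each cell's mean pairwise embedding distance to its cluster
mates and flags z > 3; clusters with fewer than three members or zero
distance variance are skipped.

## Manifold

Affinities use a Gaussian kernel over each cell's 20 nearest neighbours
with adaptive bandwidth equal to the distance to the ⌈k/3⌉-th neighbour,
symmetrized by averaging with the transpose. Diffusion maps eigendecompose
the row-normalised Markov matrix via its symmetric conjugate; the trivial
eigenvector is dropped and the top 10 components are rescaled by λ/(1−λ)
into the multiscale space used for tree fitting. The pipeline applies the
Coifman–Lafon density normalisation (α = 1) before row-normalising:
without it, the dense unspecialized pool contracts and the sparse
fate-transition regions stretch, distorting geodesic pseudotime; α is a
parameter (default 0) so the plain construction remains available. Leiden
clustering runs on the affinity graph with a fixed seed.

## Principal tree and pseudotime

SimplePPT alternates (i) soft assignments R[i,k] ∝ exp(−‖x_i − f_k‖²/σ),
(ii) a minimum spanning tree over node–node squared distances and (iii) a
penalized least-squares node update solving
(diag(Rᵀ1) + λL) F = Rᵀ X with the graph Laplacian L, from an
initialisation of cells sampled without replacement under a seed.
Convergence is declared when the maximum node displacement falls below
`tol`.

Because two of the fates overlap in expression space late in development, a
single fit merges them; the pipeline therefore fits a main tree on most
cells and a second, smaller tree on the overlapping branch's cells (the
late intermediate plus both terminal fates of the last decision, selected
in the synthetic case by the planted labels standing in for manual cluster
selection) and joins the two tip-to-tip. The secondary tree uses its own
attachment rule: it joins through its developmentally *earliest* tip (the
same aggregated-time rule as root selection) to the spatially nearest tip
of the main tree — attaching by pure spatial proximity can join through a
terminal state when two fates converge, which silently reverses the
attached branch.

Pipeline defaults at the preset scale (2,000 cells, ~7 segments): 120 + 40
nodes, σ = 0.03 / λ = 300 for the main tree and σ = 0.01 / λ = 50 for the
secondary one (the smaller tree covers a compressed region where the main
settings over-smooth its fork), fit seed 42. Node counts are a resolution
choice: hundreds of nodes at this size put a handful of cells per node and
grow spurious spurs unrelated to the method.

The root is the tip with the lowest responsibility-weighted mean
developmental time (ties to the smallest node id). Node pseudotime is
geodesic edge-length (Euclidean) distance from the root; each cell takes
the interpolated pseudotime of its clamped orthogonal projection onto the
best-fitting edge incident to its argmax-responsibility node, and inherits
that edge's segment. Subsetting preserves pseudotime values; the dendrogram
layout assigns unit lanes to leaf segments (siblings packed by subtree
size) with seeded jitter bounded by `crowdedness`.

## Trend and covariate testing

The association test fits an independent cubic B-spline of expression on
pseudotime within each segment (df = 5 basis functions per segment; for
df < 4 a polynomial of degree df, so df = 1 recovers the classical
regression F-test) and compares it to a global intercept with an F-test;
p-values are BH-corrected across genes and floored at 1e-300, and
significance additionally requires the fitted amplitude A = max − min to
exceed `A_cut` (default 0.025; 0.3 for per-trajectory exclusivity
analyses). Segments with fewer than df + 2 cells are dropped with a
warning; zero-variance genes get F = 0, p = 1.

Smoothed trends use penalized cubic regression splines per segment (ridge
on second differences of the coefficients; smoothing chosen from a
17-point log-spaced grid by generalized cross-validation); min–max
normalised trends are defined as all zeros for numerically flat genes.

The covariate tests share one spline basis: the full design is
[s(t), s(t)·1{cov}, 1{cov}] and the reduced design [s(t), 1{cov}]. The
amplitude test is the Wald F on the interaction block; the trend test is
the nested-model ANOVA — with an unpenalized basis the two statistics
coincide, and both are computed by their own route and reported
separately. Both families are BH-corrected and flagged at fdr < 0.1.

## Bifurcation analysis

`test_fork` stacks the progenitor cells into both branch fits (the
shared-smooth design) and F-tests the branch-interaction block of
[s(t), s(t)·1{branch}, 1{branch}]. The analysis is local to the fork: the
shared "pre" cells are the fork's immediate parent segment, not the whole
root path — with the root path included, the ten activation bins cannot
resolve short terminal branches. Significant genes (fdr < 0.05) are
assigned to the branch with the higher mean fitted post-fork expression
when the between-branch difference strictly exceeds the per-fork cutoff
(default 0.3). Upregulation along the progenitor-to-terminal path is an
ordinary one-sided least-squares slope.

Activation timing bins each path into 10 equal-width pseudotime bins and
computes the relative rate r(b_t) = (f(b_{t+1}) − f(b_{t−1}))/(max f −
min f) at interior bins (endpoints carry no rate); empty bins are
interpolated from neighbours so the rate stays defined. A gene activates at
the first bin whose rate strictly exceeds the threshold (default 0.25: for
10-bin trends this separates the steep central part of a sigmoidal rise,
whose centered-difference rates reach 0.3–0.7, from baseline tails around
0.1). Genes activating strictly before the fork pseudotime form the early
module; at or after it, the late module; genes with no qualifying bin get
none.

Sliding windows of pseudotime-ordered cells (default stride of half a
window, final window anchored to the end; explicit cell lists are accepted
to reproduce manual selections) yield local Pearson correlation matrices
over the two modules; intra- and inter-module means run over the
corresponding index pairs, excluding genes with zero variance in a window,
and repulsion is the mean of the two intra terms minus the inter term.

## Gene-set and ligand–receptor scoring

Per-cell gene-set activity is the area under the recovery curve of set
members within the top 5 % of that cell's expression-ranked genes (ties
broken by stable gene order), normalised by the maximal achievable area —
scores are rank-based and invariant to monotone transforms of a cell's
profile. Ligand–receptor scoring follows the permutation recipe: a partner
(possibly multi-subunit) scores the minimum over subunits of the subunit's
mean log-normalised expression in the cluster; a partner counts as
expressed only when every subunit is detected (count > 0) in more than 10 %
of the cluster's cells, else the directed pair is undefined; the pair score
is the mean of the two partner scores, and the one-sided p-value uses
add-one smoothing over seeded label permutations, so p ∈ [1/(n_perm+1), 1].

## Validation scope and problem sizes

The test suite and the acceptance script run at desk scale: 2,000-cell
simulations for the pipeline, 300–500 cells and a few hundred genes for the
statistical calibrations, 999 permutations for ligand–receptor tests, and
1,000 random vectors against the brute-force activation-rate oracle. The
bifurcation-recovery checks evaluate the fork statistics on the planted
pseudotime and branch labels — they validate the tests themselves; the
separate tree checks quantify how well the fitted tree reproduces those
inputs. Passing on synthetic data shows the machinery is correct and
calibrated under the generator's assumptions (independent NB noise given
the programs, batch-free manifold, binary forks); it does not certify
performance on real data with batch structure, regulatory co-variation or
non-binary decisions.

## Known limitations

- Pseudotime accuracy is bounded by the information in the expression
  itself; in slow stretches of the trajectory the recovered ordering
  saturates near the supervised ceiling (~0.78 rank correlation within the
  unspecialized window of the preset) regardless of analysis settings.
- SimplePPT topology is sensitive to σ/λ at fixed node budget: too little
  smoothing grows spurious tips, too much merges close forks. The defaults
  favour exact topology at the preset scale; spur pruning beyond collapsing
  degree-2 chains is deliberately not implemented.
- The z > 3 doublet screen is only as good as its embedding: on
  manifold-denoising embeddings (diffusion coordinates) a substantial
  fraction of true doublets is pulled back onto the manifold and scores
  below threshold, which is why the pipeline prefers annotated clusters
  plus the faithful (latent) embedding for synthetic data.
- The covariate amplitude and trend tests are identical under the
  unpenalized basis; they would differ under penalized smooths with
  effective-degrees-of-freedom accounting, which is out of scope.
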