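# branchforge

Branched-trajectory analysis for single-cell transcriptomics, built around
the workflow used to map the diversification of spiral ganglion neurons
(SGNs) — the primary auditory afferents — from an unspecialized embryonic
pool into the I_a, I_b, I_c and type II subtypes through three ordered
binary fate decisions.

The package provides, as composable modules:

- **synthio** — a synthetic-data generator that emulates the statistical
  structure of such an experiment: ~2,000 Smart-seq2-like cells sampled from
  overlapping developmental windows along a rooted binary lineage tree,
  genes organised into constant, monotone-maturation, pre-bifurcation
  "early" (competing) and post-bifurcation "late" (exclusive) programs, a
  glial contamination code tied to a marker gene, planted cross-fate
  doublets and per-cell spike-in fractions; plus MatrixMarket/TSV readers
  and writers.
- **preprocess** — threshold QC (detected genes, spike-in fraction), depth
  normalisation with log1p, overdispersed-gene selection from the
  mean–variance trend, contamination-code detection (genes with Pearson
  r > 0.3 against the marker) and removal, and embedding-distance doublet
  flagging (within-cluster z > 3 on mean pairwise distance).
- **manifold** — adaptive-bandwidth Gaussian KNN affinities, diffusion maps
  with the multiscale scaling λ/(1−λ), and Leiden clustering.
- **tree** — SimplePPT principal trees: alternating soft assignment
  R ∝ exp(−‖x−f‖²/σ), minimum-spanning-tree re-estimation and
  λ-penalised node updates; tip-to-tip attachment of two separately fitted
  trees; root selection by lowest aggregated developmental time; geodesic
  pseudotime with per-cell edge projection; tree subsetting and dendrogram
  layout.
- **trends** — branch-wise cubic-spline association F-tests
  (exp_i ~ t_i per segment against a flat model, BH correction, amplitude
  cutoff), penalized-spline trend fitting with GCV, and the two covariate
  tests g ~ s(t) + s(t):Covariate + Covariate for populations sharing one
  trajectory.
- **forks** — bifurcation analysis: the branch-interaction test
  g ~ s(t) + s(t):Branch + Branch, one-sided upregulation slopes, branch
  assignment with per-fork expression cutoffs, activation timing from the
  10-bin relative rate r(b_t) = (f(b_{t+1}) − f(b_{t−1})) / (max f − min f),
  early/late module splitting at the fork, and sliding-window
  intra-/inter-module correlation ("repulsion") analysis.
- **comms** — recovery-AUC gene-set (regulon activity) scoring and
  CellPhoneDB-style permutation ligand–receptor tests with the min-subunit
  complex rule.

## Worked example

```python
import branchforge as bf
import branchforge.trends as tr
from scipy.stats import spearmanr

res = bf.pipeline.run_sgn_pipeline(seed=0)   # simulate + analyse end to end
t = res.ptree
truth = res.clean.cell_meta["true_pseudotime"].reindex(t.cell_names)
print(f"cells after cleanup: {res.clean.n_cells}")
print(f"glial code size: {len(res.glial_code.code_genes)} genes")
print(f"doublets flagged: {len(res.doublets_flagged)}")
print(f"tree: {len(t.leaves)} leaves, {len(t.forks)} forks")
print(f"pseudotime Spearman rho vs planted truth: "
      f"{spearmanr(t.cell_pseudotime, truth).statistic:.3f}")

expr = bf.pipeline.align_expression(res.clean, t)
assoc = tr.test_association(expr, t.cell_pseudotime, t.cell_segment)
print(f"tree-associated features: {int(assoc['significant'].sum())}")
```

prints

```
cells after cleanup: 1886
glial code size: 21 genes
doublets flagged: 41
tree: 4 leaves, 3 forks
pseudotime Spearman rho vs planted truth: 0.920
tree-associated features: 169
```

The four leaves are the terminal fates, the three forks the ordered fate
decisions; the glial code contains the marker plus its 20 planted
followers; the recovered pseudotime rank-matches the planted ordering.

The same workflow runs from a shell:

```bash
branchforge simulate --preset sgn --cells 2000 --seed 0 --out raw/
branchforge preprocess --in raw/ --out clean/ --min-genes 50
branchforge manifold   --in clean/ --out clean/
branchforge tree       --in clean/ --out clean/ --sigma 0.03 --lam 300
branchforge trends     --in clean/ --out clean/
```

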