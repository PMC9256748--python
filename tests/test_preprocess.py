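"""QC thresholds, normalisation, overdispersion, glial code, doublets."""

import warnings

import numpy as np
import pandas as pd
import pytest

import branchforge.preprocess as pp
import branchforge.synthio as sy


def _toy(counts, spike=None, names=None):
    counts = np.asarray(counts, dtype=np.int64)
    cells = pd.Index(names or [f"c{i}" for i in range(counts.shape[0])], name="cell")
    meta = pd.DataFrame(index=cells)
    if spike is not None:
        meta["spikein_fraction"] = spike
    genes = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(counts.shape[1])],
                                        name="gene"))
    return sy.ExpressionData(counts=counts, cell_meta=meta, gene_meta=genes)


class TestQC:
    def test_five_cell_fixture_keeps_exactly_one(self, five_cell_qc_fixture):
        kept = pp.qc_filter(five_cell_qc_fixture, pp.QCThresholds(1000, 0.05))
        assert kept.n_cells == 1
        assert kept.cell_names[0] == "c4"  # 3000 genes, 0 spike-in

    def test_thresholds_are_strict(self):
        data = _toy(np.ones((1, 1000)), spike=[0.05])
        assert pp.qc_filter(data, pp.QCThresholds(1000, 0.05)).n_cells == 0
        data2 = _toy(np.ones((1, 1001)), spike=[0.049])
        assert pp.qc_filter(data2, pp.QCThresholds(1000, 0.05)).n_cells == 1

    def test_idempotent(self, five_cell_qc_fixture):
        thr = pp.QCThresholds(1000, 0.05)
        once = pp.qc_filter(five_cell_qc_fixture, thr)
        twice = pp.qc_filter(once, thr)
        assert list(once.cell_names) == list(twice.cell_names)


class TestNormalize:
    def test_hand_computed_example(self):
        data = _toy([[1, 1]])
        out = pp.normalize_log(data, target_sum=1000)
        assert np.allclose(out.norm, np.log(501))

    def test_rowsums_match_target(self, sgn_norm):
        back = np.expm1(sgn_norm.norm).sum(axis=1)
        assert np.allclose(back, 1000.0)

    def test_zero_gene_stays_zero(self):
        data = _toy([[5, 0], [3, 0]])
        out = pp.normalize_log(data)
        assert np.all(out.norm[:, 1] == 0)

    def test_zero_count_cells_dropped_with_warning(self):
        data = _toy([[1, 1], [0, 0]])
        with pytest.warns(UserWarning):
            out = pp.normalize_log(data)
        assert out.n_cells == 1

    def test_bad_target_sum(self):
        with pytest.raises(ValueError):
            pp.normalize_log(_toy([[1]]), target_sum=0)


class TestOverdispersed:
    def test_bimodal_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        # Poisson genes spanning a range of means anchor the trend
        means = rng.uniform(2, 30, 30)
        counts = rng.poisson(means[None, :], (200, 30))
        counts[:100, 0] = 0
        counts[100:, 0] = 40
        data = pp.normalize_log(_toy(counts))
        assert pp.find_overdispersed(data, n_top=5)[0] == "g0"

    def test_deterministic(self, sgn_norm):
        assert pp.find_overdispersed(sgn_norm) == pp.find_overdispersed(sgn_norm)

    def test_n_top_boundary(self, sgn_norm):
        got = pp.find_overdispersed(sgn_norm, n_top=sgn_norm.n_genes)
        assert len(got) == sgn_norm.n_genes


class TestGlialCode:
    def test_marker_in_its_own_code(self, sgn_norm):
        code = pp.compute_glial_code(sgn_norm, "Sox10", 0.3)
        assert "Sox10" in code.code_genes.index
        assert np.isclose(code.code_genes["Sox10"], 1.0)

    def test_linear_function_of_marker_included(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, (100, 3))
        counts[:, 1] = 2 * counts[:, 0] + 3
        data = _toy(counts)
        data.norm = data.counts.astype(float)  # raw layer: exact linearity
        code = pp.compute_glial_code(data, "g0", 0.3)
        assert "g1" in code.code_genes.index
        assert np.isclose(code.code_genes["g1"], 1.0)

    def test_affine_marker_transform_invariance(self, sgn_norm):
        base = pp.compute_glial_code(sgn_norm, "Sox10", 0.3)
        shifted = sgn_norm.copy()
        shifted.norm = sgn_norm.norm.copy()
        j = shifted.gene_names.get_loc("Sox10")
        shifted.norm[:, j] = 3.0 * shifted.norm[:, j] + 2.0
        again = pp.compute_glial_code(shifted, "Sox10", 0.3)
        assert set(base.code_genes.index) == set(again.code_genes.index)

    def test_planted_code_recovery(self, sgn_norm):
        code = pp.compute_glial_code(sgn_norm, "Sox10", 0.3)
        planted = {g for g in sgn_norm.gene_names if g.startswith("glia")} | {"Sox10"}
        found = set(code.code_genes.index)
        assert len(found & planted) / len(planted) >= 0.95
        others = set(sgn_norm.gene_names) - planted
        assert len(found - planted) / len(others) <= 0.01

    def test_absent_marker_errors(self, sgn_norm):
        with pytest.raises(ValueError):
            pp.compute_glial_code(sgn_norm, "NotAGene", 0.3)


class TestRemoveGenes:
    def test_empty_removal_is_identity(self, sgn_norm):
        out = pp.remove_genes(sgn_norm, [])
        assert np.array_equal(out.counts, sgn_norm.counts)

    def test_remove_all(self, sgn_norm):
        out = pp.remove_genes(sgn_norm, list(sgn_norm.gene_names))
        assert out.n_genes == 0
        assert out.n_cells == sgn_norm.n_cells

    def test_detected_gene_counts_not_recomputed(self, sgn_norm):
        out = pp.remove_genes(sgn_norm, [sgn_norm.gene_names[0]])
        assert out.cell_meta["n_detected_genes"].equals(
            sgn_norm.cell_meta["n_detected_genes"]
        )

    def test_code_removal_eliminates_mirror_structure(self, sgn_norm):
        code = pp.compute_glial_code(sgn_norm, "Sox10", 0.3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cleaned = pp.remove_genes(sgn_norm, list(code.code_genes.index))
        X = cleaned.norm
        j = sgn_norm.gene_names.get_loc("Sox10")
        marker = sgn_norm.norm[:, j]
        cors = np.array([
            np.corrcoef(X[:, k], marker)[0, 1] for k in range(cleaned.n_genes)
        ])
        # only chance-level correlations with the contaminant remain
        assert (cors > 0.3).mean() <= 0.01


class TestDoubletEmbedding:
    def test_constructed_outlier_is_flagged(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 0.01, (10, 2)), [[5.0, 5.0]]])
        clusters = np.zeros(11, dtype=int)
        flagged = pp.detect_doublets_embedding(emb, clusters, [0], z_cutoff=3.0)
        assert flagged == [10]

    def test_uniform_cluster_skipped_with_warning(self):
        emb = np.zeros((4, 2))  # co-located points: zero distance variance
        with pytest.warns(UserWarning):
            flagged = pp.detect_doublets_embedding(emb, np.zeros(4), [0], 3.0)
        assert flagged == []

    def test_unselected_clusters_never_flagged(self):
        rng = np.random.default_rng(1)
        emb = np.vstack([rng.normal(0, 0.01, (10, 2)), [[9.0, 9.0]]])
        clusters = np.zeros(11, dtype=int)
        assert pp.detect_doublets_embedding(emb, clusters, [], 3.0) == []
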