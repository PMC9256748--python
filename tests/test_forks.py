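"""Bifurcation analysis: interaction tests, activation rates, modules,
sliding-window correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import branchforge.forks as fk


class TestActivation:
    def test_worked_step_example(self):
        f = [0, 0, 0, 1, 2, 3, 3, 3, 3, 3]
        rates, bin1, pt = fk.activation(f, 0.5, np.arange(10) + 0.5)
        assert np.isclose(rates[1], 1 / 3)  # interior bin 3 (1-based)
        assert np.isclose(rates[2], 2 / 3)  # interior bin 4
        assert bin1 == 4
        assert pt == 3.5

    def test_linear_trend_has_constant_rate(self):
        f = np.linspace(0, 9, 10)
        rates, _, _ = fk.activation(f, 10.0, np.arange(10))
        assert np.allclose(rates, 2 / 9)

    def test_zero_threshold_triggers_at_first_rise(self):
        f = [0, 0, 0, 0, 1, 2, 3, 3, 3, 3]
        _, bin1, _ = fk.activation(f, 0.0, np.arange(10))
        assert bin1 == 4  # first interior bin with positive centered diff

    def test_flat_trend_is_degenerate(self):
        with pytest.raises(ValueError):
            fk.activation(np.ones(10), 0.1, np.arange(10))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random(10) * rng.uniform(0.5, 3)
        if f.max() - f.min() <= 0:
            return
        rates, _, _ = fk.activation(f, 0.3, np.arange(10.0))
        oracle = np.array(
            [(f[t + 1] - f[t - 1]) / (f.max() - f.min()) for t in range(1, 9)]
        )
        assert np.allclose(rates, oracle, atol=1e-12)


class TestUpregulation:
    def test_increasing_and_decreasing_genes(self):
        pt = np.linspace(0, 1, 30)
        s_up, p_up = fk.test_upregulation(pt * 2, pt)
        assert s_up > 0 and p_up < 1e-10
        s_dn, p_dn = fk.test_upregulation(-pt, pt)
        assert s_dn < 0 and p_dn > 0.999

    def test_hand_computed_five_point_slope(self):
        pt = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        slope, _ = fk.test_upregulation(y, pt)
        tc = pt - pt.mean()
        assert np.isclose(slope, (tc @ (y - y.mean())) / (tc @ tc))
        assert np.isclose(slope, 0.8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fk.test_upregulation([1, 2], [0, 1])
        with pytest.raises(ValueError):
            fk.test_upregulation([1, 2, 3], [1, 1, 1])


class TestAssignBranch:
    def _frame(self, diffs):
        mean_fitted = pd.DataFrame(
            {"L": np.zeros(len(diffs)), "R": -np.asarray(diffs)},
            index=[f"g{i}" for i in range(len(diffs))],
        )
        fdr = pd.Series(0.0, index=mean_fitted.index)
        return fdr, mean_fitted

    def test_difference_at_cutoff_is_unassigned(self):
        fdr, mf = self._frame([0.3])
        assert fk.assign_branch(fdr, mf, cutoff=0.3)["g0"] is None

    def test_infinite_cutoff_assigns_nothing(self):
        fdr, mf = self._frame([5.0, 3.0])
        assert fk.assign_branch(fdr, mf, cutoff=np.inf).isna().all()

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(0)
        mf = pd.DataFrame(
            {"L": rng.normal(0, 1, 30), "R": rng.normal(0, 1, 30)},
            index=[f"g{i}" for i in range(30)],
        )
        fdr = pd.Series(rng.uniform(0, 0.2, 30), index=mf.index)
        fwd = fk.assign_branch(fdr, mf, cutoff=0.3)
        relabelled = mf.rename(columns={"L": "R", "R": "L"})[["L", "R"]]
        rev = fk.assign_branch(fdr, relabelled, cutoff=0.3)
        swap = {"L": "R", "R": "L", None: None}
        assert all(rev[g] == swap[fwd[g]] for g in mf.index)

    def test_high_fdr_blocks_assignment(self):
        fdr, mf = self._frame([5.0])
        fdr[:] = 0.2
        assert fk.assign_branch(fdr, mf, cutoff=0.3, fdr_cut=0.05)["g0"] is None


class TestForkTest:
    def _fork_sim(self, rng, n=400, amp=1.5):
        pt = rng.uniform(0, 1, n)
        branch = np.where(pt < 0.4, "pre", np.where(rng.random(n) < 0.5, "L", "R"))
        rise = amp / (1 + np.exp(-(pt - 0.55) / 0.08))
        mean = np.where(branch == "L", rise, 0.0)
        return pt, branch, mean

    def test_identical_branches_are_null(self):
        rng = np.random.default_rng(0)
        pt, branch, _ = self._fork_sim(rng)
        Y = pd.DataFrame(rng.normal(0, 0.5, (len(pt), 100)))
        res = fk.test_fork(Y, pt, branch)
        assert (res["fdr"] < 0.1).mean() <= 0.05

    def test_branch_specific_rise_detected(self):
        rng = np.random.default_rng(1)
        pt, branch, mean = self._fork_sim(rng, amp=1.5)
        Y = pd.DataFrame(mean[:, None] + rng.normal(0, 0.5, (len(pt), 100)))
        res = fk.test_fork(Y, pt, branch)
        assert (res["fdr"] < 0.1).mean() >= 0.95

    def test_permuted_branch_labels_kill_detection(self):
        rng = np.random.default_rng(2)
        pt, branch, mean = self._fork_sim(rng, amp=1.5)
        Y = pd.DataFrame(mean[:, None] + rng.normal(0, 0.5, (len(pt), 60)))
        post = branch != "pre"
        perm = branch.copy()
        perm[post] = rng.permutation(branch[post])
        res = fk.test_fork(Y, pt, perm)
        assert (res["fdr"] < 0.1).mean() <= 0.1


class TestSlideCors:
    def test_perfectly_correlated_modules_hit_extremes(self):
        n = 40
        base = np.linspace(-1, 1, n)
        expr = pd.DataFrame(
            {"a1": base, "a2": 2 * base, "b1": -base, "b2": -3 * base}
        )
        wins = fk.slide_cors(expr, np.arange(n), ["a1", "a2"], ["b1", "b2"],
                             window_size=n)
        w = wins[0]
        assert np.isclose(w.intra_A, 1.0) and np.isclose(w.intra_B, 1.0)
        assert np.isclose(w.inter, -1.0)
        assert np.isclose(w.repulsion, 2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        n, g = 60, 8
        expr = pd.DataFrame(rng.normal(0, 1, (n, g)),
                            columns=[f"g{i}" for i in range(g)])
        pt = rng.uniform(0, 1, n)
        ma, mb = [f"g{i}" for i in range(4)], [f"g{i}" for i in range(4, 8)]
        wins = fk.slide_cors(expr, pt, ma, mb, window_size=30, stride=15)
        order = np.argsort(pt, kind="stable")
        M = expr.to_numpy()[order]
        for w in wins:
            lo = list(order).index(w.cells[0])
            W = M[lo:lo + 30]
            C = np.corrcoef(W, rowvar=False)
            intra_a = np.mean([C[i, j] for i in range(4) for j in range(4) if j > i])
            intra_b = np.mean([C[i, j] for i in range(4, 8) for j in range(4, 8) if j > i])
            inter = np.mean([C[i, j] for i in range(4) for j in range(4, 8)])
            assert abs(w.intra_A - intra_a) < 1e-12
            assert abs(w.intra_B - intra_b) < 1e-12
            assert abs(w.inter - inter) < 1e-12
            assert abs(w.repulsion - (np.mean([intra_a, intra_b]) - inter)) < 1e-12

    def test_invariant_to_affine_gene_rescaling(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(0, 1, (50, 6)),
                            columns=[f"g{i}" for i in range(6)])
        pt = rng.uniform(0, 1, 50)
        ma, mb = ["g0", "g1", "g2"], ["g3", "g4", "g5"]
        base = fk.slide_cors(expr, pt, ma, mb, window_size=25)
        expr2 = expr.copy()
        expr2["g1"] = 5.0 * expr2["g1"] - 3.0
        again = fk.slide_cors(expr2, pt, ma, mb, window_size=25)
        for w1, w2 in zip(base, again):
            assert np.isclose(w1.repulsion, w2.repulsion)

    def test_zero_variance_gene_excluded_with_warning(self):
        expr = pd.DataFrame(
            {"g0": np.arange(10.0), "g1": np.ones(10),
             "g2": -np.arange(10.0), "g3": np.arange(10.0) ** 2}
        )
        with pytest.warns(UserWarning):
            wins = fk.slide_cors(expr, np.arange(10), ["g0", "g1"], ["g2", "g3"],
                                 window_size=10)
        assert np.isfinite(wins[0].inter)

    def test_disjoint_modules_required(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)),
                            columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            fk.slide_cors(expr, np.arange(20), ["a", "b"], ["b", "c"], window_size=10)


def test_split_modules_boundary_and_empty():
    act = pd.Series([0.5, 0.49, np.nan], index=["at", "before", "none"])
    out = fk.split_modules(act, fork_pseudotime=0.5)
    assert out["at"] == "late"       # activation exactly at the fork
    assert out["before"] == "early"
    assert out["none"] is None
    empty = fk.split_modules(pd.Series(dtype=float), 0.5)
    assert len(empty) == 0
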