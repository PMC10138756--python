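import numpy as np
import pandas as pd
import pytest

from isoplex.expression import (
    bh_adjust,
    cluster_profiles,
    deg_pairwise,
    fpkm,
    pca,
    term_enrichment,
)


class TestFpkm:
    def test_unit_case(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        lengths = pd.Series({"g": 1000})
        out = fpkm(counts, lengths, pd.Series({"s": 1_000_000}))
        assert out.loc["g", "s"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        counts = pd.DataFrame({"s": [0, 5]}, index=["a", "b"])
        out = fpkm(counts, pd.Series({"a": 500, "b": 500}))
        assert out.loc["a", "s"] == 0

    def test_doubling_counts_leaves_fpkm_unchanged(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 100, (20, 3)),
                              index=[f"g{i}" for i in range(20)],
                              columns=list("abc"))
        lengths = pd.Series(rng.integers(200, 3000, 20), index=counts.index)
        assert np.allclose(fpkm(counts, lengths), fpkm(counts * 2, lengths))

    def test_exact_inversion_recovers_counts(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 100, (10, 2)),
                              index=[f"g{i}" for i in range(10)],
                              columns=list("ab"))
        lengths = pd.Series(rng.integers(100, 2000, 10), index=counts.index)
        lib = counts.sum(axis=0)
        out = fpkm(counts, lengths)
        back = out.mul(lengths, axis=0).mul(lib, axis=1) / 1e9
        assert np.allclose(back, counts)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm(pd.DataFrame({"s": [1]}, index=["g"]), pd.Series({"g": 0}))


class TestPca:
    def test_identical_samples_share_scores(self):
        m = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3], "c": [9, 1, 4]})
        scores, _, _ = pca(m, n_components=2)
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.uniform(0, 50, (30, 6)),
                         columns=[f"s{i}" for i in range(6)])
        _, evr, _ = pca(m, n_components=5)
        assert evr.sum() <= 1 + 1e-9
        assert all(evr[i] >= evr[i + 1] - 1e-12 for i in range(len(evr) - 1))

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0, 100, (10, 10)),
                         columns=[f"s{i}" for i in range(10)])
        scores, evr, _ = pca(m, log_transform=True, n_components=3)
        x = np.log2(m.to_numpy().T + 1)
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(3):
            proj = xc @ v[:, i]
            got = scores.iloc[:, i].to_numpy()
            # same axis up to sign
            assert np.allclose(np.abs(proj), np.abs(got), atol=1e-8)
        assert np.allclose(evr, (w / w.sum())[:3])

    def test_distinct_group_separates_on_pc1(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(1, 10, 50)
        cols = {}
        for i in range(5):
            shift = 40.0 if i >= 3 else 0.0
            cols[f"s{i}"] = base + shift + rng.normal(0, 0.1, 50)
        m = pd.DataFrame(cols)
        scores, _, _ = pca(m, n_components=1)
        pc1 = scores["PC1"]
        assert max(pc1[:3]) < min(pc1[3:]) or min(pc1[:3]) > max(pc1[3:])


class TestClusterProfiles:
    def _two_shapes(self, n=40):
        rng = np.random.default_rng(5)
        rows, ids = [], []
        for i in range(n):
            shape = np.array([10, 10, 1, 1, 1, 1]) if i % 2 else np.array(
                [1, 1, 1, 1, 10, 10])
            rows.append(shape + rng.normal(0, 0.2, 6))
            ids.append(f"g{i}")
        return pd.DataFrame(rows, index=ids)

    def test_perfect_recovery_of_two_planted_shapes(self):
        from sklearn.metrics import adjusted_rand_score

        m = self._two_shapes()
        labels, means = cluster_profiles(m, k=2, seed=0)
        truth = [i % 2 for i in range(len(m))]
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        assert set(labels) == {1, 2}

    def test_k_one_puts_everything_together(self):
        labels, _ = cluster_profiles(self._two_shapes(), k=1, seed=0)
        assert set(labels) == {1}

    def test_row_permutation_leaves_assignment_by_id_unchanged(self):
        m = self._two_shapes()
        l1, _ = cluster_profiles(m, k=2, seed=0)
        l2, _ = cluster_profiles(m.iloc[::-1], k=2, seed=0)
        assert l1.sort_index().equals(l2.sort_index())

    def test_zero_variance_rows_dropped(self):
        m = self._two_shapes()
        m.loc["flat"] = 3.0
        labels, _ = cluster_profiles(m, k=2, seed=0)
        assert "flat" not in labels.index


class TestDegPairwise:
    matrix = pd.DataFrame(
        {"a": [31.0, 0.0, 3.0], "b": [7.0, 0.0, 3.0]},
        index=["up", "silent", "flat"],
    )

    def test_fold_change_call(self):
        table, union = deg_pairwise(self.matrix, [("a", "b")])
        t = table.set_index("gene_id")
        assert t.loc["up", "log2_fc"] == pytest.approx(2.0)
        assert union == {"up"}

    def test_zero_vs_zero_not_deg(self):
        table, union = deg_pairwise(self.matrix, [("a", "b")])
        assert "silent" not in union and "flat" not in union

    def test_symmetric_in_pair_order(self):
        _, u1 = deg_pairwise(self.matrix, [("a", "b")])
        _, u2 = deg_pairwise(self.matrix, [("b", "a")])
        assert u1 == u2


class TestTermEnrichment:
    def test_combinatorial_example(self):
        universe = {f"g{i}" for i in range(10)}
        term_map = {"T": {f"g{i}" for i in range(5)}}
        selected = {"g0", "g1", "g2", "g3"}
        out = term_enrichment(selected, universe, term_map)
        assert out.iloc[0].p_value == pytest.approx(5 / 210)

    def test_selected_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        term_map = {"T1": {"g0", "g1"}, "T2": {"g3"}}
        out = term_enrichment(set(universe), universe, term_map)
        assert np.allclose(out.p_value, 1.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(set(), {"g"}, {})

    def test_selection_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment({"x"}, {"g"}, {})


class TestBhAdjust:
    def test_textbook_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_min_formula_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        order = np.argsort(p)
        m = len(p)
        # q_(i) = min_{j >= i} p_(j) * m / j on the sorted scale
        sorted_q = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(sorted_q, 1.0)
        assert np.allclose(q, oracle)
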