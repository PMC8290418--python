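import numpy as np
import pandas as pd
import pytest

from nsclc_scmet import pathway_activity as pa
from nsclc_scmet.io_formats import ExpressionMatrix, GeneSetCollection


def brute_force_score(m, labels, gsc, weights):
    """Independent double-loop oracle for A(P,c)."""
    labels = np.asarray(labels)
    clusters = sorted(set(labels))
    out = {}
    for name, genes in gsc.sets.items():
        out[name] = {}
        for c in clusters:
            num = den = 0.0
            for g in genes:
                i = m.gene_ids.index(g)
                cluster_vals = [m.values[i, j] for j in range(m.n_cells) if labels[j] == c]
                all_vals = [m.values[i, j] for j in range(m.n_cells)]
                r = (sum(cluster_vals) / len(cluster_vals)) / (sum(all_vals) / len(all_vals))
                num += weights[g] * r
                den += weights[g]
            out[name][str(c)] = num / den
    return out


class TestRelativeExpression:
    def test_constant_gene_is_one_everywhere(self):
        m = ExpressionMatrix(np.full((1, 4), 3.0), ["g"], list("abcd"),
                             layer_tag="normalized")
        r = pa.relative_expression(m, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(r.to_numpy(), 1.0)

    def test_hand_worked_ratio(self):
        m = ExpressionMatrix(np.array([[2.0, 2.0, 1.0, 1.0]]), ["g"], list("abcd"),
                             layer_tag="normalized")
        r = pa.relative_expression(m, np.array(["A", "A", "B", "B"]))
        assert r.loc["g", "A"] == pytest.approx(4 / 3)
        assert r.loc["g", "B"] == pytest.approx(2 / 3)

    def test_equal_cluster_sizes_mean_identity(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(rng.random((5, 6)) + 0.1, [f"g{i}" for i in range(5)],
                             [f"c{j}" for j in range(6)], layer_tag="normalized")
        r = pa.relative_expression(m, np.repeat([0, 1, 2], 2))
        np.testing.assert_allclose(r.mean(axis=1), 1.0)

    def test_single_cluster_is_error(self):
        m = ExpressionMatrix(np.ones((2, 3)), ["g0", "g1"], list("abc"),
                             layer_tag="normalized")
        with pytest.raises(ValueError, match="2 clusters"):
            pa.relative_expression(m, np.zeros(3))


class TestWeights:
    @pytest.mark.parametrize("n_pathways,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_reciprocal_membership(self, n_pathways, expected):
        sets = {f"P{i}": ["shared", f"own{i}"] for i in range(n_pathways)}
        w = pa.pathway_weights(GeneSetCollection(sets))
        assert w["shared"] == expected


class TestGeneFilters:
    def test_all_zero_gene_always_dropped(self):
        m = ExpressionMatrix(np.array([[0, 0], [1, 1], [2, 1], [1, 2], [3, 1], [1, 1]],
                                      dtype=float),
                             [f"g{i}" for i in range(6)], ["a", "b"],
                             layer_tag="normalized")
        gsc = GeneSetCollection({"P": [f"g{i}" for i in range(6)]})
        out, _ = pa.filter_pathway_genes(m, gsc, min_genes=5)
        assert "g0" not in out.sets["P"]

    def test_pathway_below_min_genes_dropped(self):
        m = ExpressionMatrix(np.ones((6, 2)), [f"g{i}" for i in range(6)], ["a", "b"],
                             layer_tag="normalized")
        gsc = GeneSetCollection({"small": ["g0", "g1", "g2", "g3"],
                                 "big": ["g0", "g1", "g2", "g3", "g4"]})
        out, report = pa.filter_pathway_genes(m, gsc, min_genes=5)
        assert set(out.sets) == {"big"}
        assert not report.loc[report["pathway"] == "small", "kept"].item()

    def test_permissive_thresholds_identity(self):
        m = ExpressionMatrix(np.ones((5, 2)), [f"g{i}" for i in range(5)], ["a", "b"],
                             layer_tag="normalized")
        gsc = GeneSetCollection({"P": [f"g{i}" for i in range(5)]})
        out, _ = pa.filter_pathway_genes(m, gsc, min_mean=0, max_zero_fraction=1,
                                         min_genes=1)
        assert out.sets == gsc.sets


class TestScore:
    def test_worked_fixture(self, worked_pathway_fixture):
        m, labels, gsc = worked_pathway_fixture
        r = pa.relative_expression(m, labels)
        w = pa.pathway_weights(gsc)
        A = pa.score_activity(r, w, gsc)
        assert A.loc["P1", "A"] == pytest.approx(19 / 18, abs=1e-12)
        assert A.loc["P1", "B"] == pytest.approx(17 / 18, abs=1e-12)

    def test_all_ones_scores_one(self):
        m = ExpressionMatrix(np.ones((5, 4)), [f"g{i}" for i in range(5)],
                             list("abcd"), layer_tag="normalized")
        gsc = GeneSetCollection({"P": [f"g{i}" for i in range(5)]})
        A = pa.score_activity(pa.relative_expression(m, np.array([0, 0, 1, 1])),
                              pa.pathway_weights(gsc), gsc)
        np.testing.assert_allclose(A.to_numpy(), 1.0)

    def test_oracle_equivalence_small_random(self):
        rng = np.random.default_rng(7)
        m = ExpressionMatrix(rng.random((12, 18)) + 0.05,
                             [f"g{i}" for i in range(12)],
                             [f"c{j}" for j in range(18)], layer_tag="normalized")
        labels = rng.integers(0, 3, 18)
        gsc = GeneSetCollection({
            "P1": ["g0", "g1", "g2", "g3"],
            "P2": ["g2", "g3", "g4", "g5", "g6"],
            "P3": ["g6", "g10", "g11"],
        })
        w = pa.pathway_weights(gsc)
        A = pa.score_activity(pa.relative_expression(m, labels), w, gsc)
        oracle = brute_force_score(m, labels, gsc, w)
        for name in gsc.sets:
            for c in A.columns:
                assert A.loc[name, c] == pytest.approx(oracle[name][c], abs=1e-12)

    def test_monotone_in_planted_fold(self):
        """Inflating one pathway's genes in one cluster strictly raises its score."""
        rng = np.random.default_rng(8)
        values = rng.random((10, 20)) + 0.5
        labels = np.repeat([0, 1], 10)
        gsc = GeneSetCollection({"P": ["g0", "g1", "g2"], "Q": ["g5", "g6"]})
        w = pa.pathway_weights(gsc)

        def score(vals):
            m = ExpressionMatrix(vals, [f"g{i}" for i in range(10)],
                                 [f"c{j}" for j in range(20)], layer_tag="normalized")
            return pa.score_activity(pa.relative_expression(m, labels), w, gsc)

        base = score(values)
        boosted = values.copy()
        boosted[np.ix_([0, 1, 2], labels == 0)] *= 1.5
        assert score(boosted).loc["P", "0"] > base.loc["P", "0"]


class TestPermutation:
    def test_extreme_observed_score_gets_add_one_minimum(self):
        # one pathway hugely upregulated in cluster 0 -> p_up = 1/(n_perm+1);
        # 40 cells so no random permutation recreates the observed partition
        values = np.ones((6, 40))
        values[np.ix_(range(3), range(20))] = 50.0
        m = ExpressionMatrix(values, [f"g{i}" for i in range(6)],
                             [f"c{j}" for j in range(40)], layer_tag="normalized")
        labels = np.repeat([0, 1], 20)
        gsc = GeneSetCollection({"P": ["g0", "g1", "g2"]})
        w = pa.pathway_weights(gsc)
        _, p_up, _ = pa.permutation_test(m, labels, gsc, w, n_perm=999, seed=0)
        assert p_up.loc["P", "0"] == pytest.approx(1 / 1000)

    def test_constant_matrix_gives_p_one(self):
        m = ExpressionMatrix(np.ones((5, 8)), [f"g{i}" for i in range(5)],
                             [f"c{j}" for j in range(8)], layer_tag="normalized")
        gsc = GeneSetCollection({"P": [f"g{i}" for i in range(5)]})
        w = pa.pathway_weights(gsc)
        _, p_up, p_down = pa.permutation_test(m, np.repeat([0, 1], 4), gsc, w,
                                              n_perm=99, seed=1)
        assert np.all(p_up.to_numpy() == 1.0)
        assert np.all(p_down.to_numpy() == 1.0)

    def test_same_seed_identical_p(self):
        rng = np.random.default_rng(9)
        m = ExpressionMatrix(rng.random((8, 16)) + 0.1, [f"g{i}" for i in range(8)],
                             [f"c{j}" for j in range(16)], layer_tag="normalized")
        gsc = GeneSetCollection({"P": ["g0", "g1", "g2", "g3", "g4"]})
        w = pa.pathway_weights(gsc)
        labels = rng.integers(0, 2, 16)
        r1 = pa.permutation_test(m, labels, gsc, w, n_perm=200, seed=3)
        r2 = pa.permutation_test(m, labels, gsc, w, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(r1[1], r2[1])

    def test_null_p_values_conservative(self):
        """Under an exchangeable null, P(p_up <= a) stays at or below a
        (within Monte-Carlo error), thanks to the add-one estimator."""
        rng = np.random.default_rng(10)
        gsc = GeneSetCollection({"P": [f"g{i}" for i in range(8)]})
        w = pa.pathway_weights(gsc)
        pvals = []
        for _ in range(200):
            m = ExpressionMatrix(rng.random((8, 24)) + 0.1,
                                 [f"g{i}" for i in range(8)],
                                 [f"c{j}" for j in range(24)], layer_tag="normalized")
            labels = np.repeat([0, 1], 12)
            _, p_up, _ = pa.permutation_test(m, labels, gsc, w, n_perm=99,
                                             seed=int(rng.integers(2 ** 31)))
            pvals.append(p_up.loc["P", "0"])
        pvals = np.asarray(pvals)
        for a in (0.05, 0.1, 0.25):
            se = np.sqrt(a * (1 - a) / 200)
            assert (pvals <= a).mean() <= a + 3 * se


class TestSignificant:
    def test_alpha_one_up_returns_all_above_one(self, worked_pathway_fixture):
        m, labels, gsc = worked_pathway_fixture
        res = pa.compute_pathway_activity(m, labels, gsc, n_perm=50, seed=0,
                                          min_genes=2)
        table, counts = pa.significant_pathways(res, alpha=1.0, direction="up")
        expected = int((res.score.to_numpy() > 1).sum())
        assert len(table) == expected == counts.sum()

    def test_impossible_alpha_empty(self, worked_pathway_fixture):
        m, labels, gsc = worked_pathway_fixture
        res = pa.compute_pathway_activity(m, labels, gsc, n_perm=50, seed=0,
                                          min_genes=2)
        table, _ = pa.significant_pathways(res, alpha=0.0)
        assert table.empty
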