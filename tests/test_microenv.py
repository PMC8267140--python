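import numpy as np
import pandas as pd
import pytest

from pairsig import (
    GeneSetCollection,
    differential_signatures,
    estimate_like_scores,
    gene_group_comparison,
    marker_abundance,
    score_risk_correlation,
    set_variation_score,
    tmit_classify,
)

from conftest import expr_from


class TestMarkerAbundance:
    def test_singleton_set_equals_gene_value(self, rng):
        expr = expr_from(rng.normal(5, 1, size=(4, 3)))
        scores = marker_abundance(expr, GeneSetCollection(sets={"T": ["g1"]}))
        np.testing.assert_allclose(scores.loc["T"], expr.data.loc["g1"])

    def test_constant_markers_score_constant(self):
        expr = expr_from([[3.0, 1.0], [3.0, 2.0], [9.0, 9.0]])
        scores = marker_abundance(expr, GeneSetCollection(sets={"M": ["g0", "g1"]}))
        assert scores.loc["M", "s0"] == pytest.approx(3.0)

    def test_locality(self, rng):
        vals = rng.normal(5, 1, size=(4, 3))
        expr = expr_from(vals)
        doubled = vals.copy()
        doubled[3] *= 2  # g3 is not a marker
        markers = GeneSetCollection(sets={"M": ["g0", "g1"]})
        pd.testing.assert_frame_equal(
            marker_abundance(expr, markers),
            marker_abundance(expr_from(doubled), markers),
        )

    def test_absent_markers_dropped_empty_set_errors(self, rng):
        expr = expr_from(rng.normal(size=(3, 3)))
        scores = marker_abundance(
            expr, GeneSetCollection(sets={"M": ["g0", "ghost"]})
        )
        np.testing.assert_allclose(scores.loc["M"], expr.data.loc["g0"])
        with pytest.raises(ValueError, match="'E'"):
            marker_abundance(expr, GeneSetCollection(sets={"E": ["ghost"]}))


class TestSetVariationScore:
    def test_top_gene_singleton_scores_one(self):
        expr = expr_from([[1.0, 9.0], [2.0, 1.0], [9.0, 2.0]])
        scores = set_variation_score(expr, GeneSetCollection(sets={"S": ["g2"]}))
        assert scores.loc["S", "s0"] == pytest.approx(1.0)

    def test_all_genes_score_zero(self, rng):
        expr = expr_from(rng.normal(size=(6, 4)))
        scores = set_variation_score(
            expr, GeneSetCollection(sets={"ALL": list(expr.gene_ids)})
        )
        np.testing.assert_allclose(scores.loc["ALL"], 0.0, atol=1e-12)

    def test_random_sets_mean_zero(self, rng):
        expr = expr_from(rng.normal(size=(100, 2)))
        draws = []
        for _ in range(1000):
            members = list(rng.choice(expr.gene_ids, size=10, replace=False))
            s = set_variation_score(expr, GeneSetCollection(sets={"R": members}))
            draws.append(s.loc["R", "s0"])
        # permutation expectation is exactly 0; MC tolerance ~3*sd/sqrt(n)
        assert abs(np.mean(draws)) < 0.02

    def test_monotone_transform_invariance(self, rng):
        vals = rng.lognormal(size=(20, 5))
        sets = GeneSetCollection(sets={"S": ["g0", "g3", "g7"]})
        a = set_variation_score(expr_from(vals), sets)
        b = set_variation_score(expr_from(np.log2(vals + 1)), sets)
        pd.testing.assert_frame_equal(a, b)

    def test_disjoint_set_errors(self, rng):
        expr = expr_from(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            set_variation_score(expr, GeneSetCollection(sets={"S": ["nope"]}))

    def test_scores_bounded(self, rng):
        expr = expr_from(rng.normal(size=(30, 10)))
        sets = GeneSetCollection(
            sets={f"S{i}": list(rng.choice(expr.gene_ids, 5, replace=False))
                  for i in range(5)}
        )
        scores = set_variation_score(expr, sets)
        assert (scores.to_numpy() >= -1).all() and (scores.to_numpy() <= 1).all()


class TestEstimateLikeScores:
    def test_combined_is_sum(self, rng):
        expr = expr_from(rng.normal(size=(20, 6)))
        out = estimate_like_scores(expr, ["g0", "g1"], ["g5", "g6"])
        np.testing.assert_allclose(out["combined"], out["immune"] + out["stromal"])

    def test_all_gene_sets_score_zero(self, rng):
        expr = expr_from(rng.normal(size=(10, 4)))
        out = estimate_like_scores(expr, expr.gene_ids, expr.gene_ids)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_top_ranked_immune_markers(self, rng):
        # immune markers occupy the top two ranks of sample s0
        vals = rng.uniform(1, 5, size=(20, 2))
        vals[0, 0], vals[1, 0] = 100.0, 99.0
        expr = expr_from(vals)
        out = estimate_like_scores(expr, ["g0", "g1"], ["g10", "g11"])
        assert out.loc["s0", "immune"] > 0.9
        assert out.loc["s0", "combined"] > out.loc["s0", "stromal"]


class TestDifferentialSignatures:
    def groups(self, n_a, n_b):
        return pd.Series(["a"] * n_a + ["b"] * n_b,
                         index=[f"s{i}" for i in range(n_a + n_b)])

    def test_identical_groups_flag_nothing(self, rng):
        scores = pd.DataFrame(
            np.tile(rng.normal(size=(5, 10)), (1, 2)),
            index=[f"set{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(20)],
        )
        out = differential_signatures(scores, self.groups(10, 10))
        assert out["flagged"].sum() == 0

    def test_shifted_set_flagged(self, rng):
        base = rng.normal(0, 0.1, size=(4, 100))
        base[2, 50:] += 0.5  # one set shifted between the 50/50 groups
        scores = pd.DataFrame(base, index=[f"set{i}" for i in range(4)],
                              columns=[f"s{i}" for i in range(100)])
        out = differential_signatures(scores, self.groups(50, 50))
        assert bool(out.loc["set2", "flagged"])
        assert out.loc["set2", "effect"] == pytest.approx(0.5, abs=0.1)

    def test_infinite_threshold_flags_nothing(self, rng):
        base = rng.normal(size=(3, 40))
        base[0, 20:] += 5.0
        scores = pd.DataFrame(base, index=["a", "b", "c"],
                              columns=[f"s{i}" for i in range(40)])
        out = differential_signatures(scores, self.groups(20, 20),
                                      fc_threshold=np.inf)
        assert out["flagged"].sum() == 0

    def test_constant_scores_p_one(self):
        scores = pd.DataFrame(np.ones((1, 10)), index=["flat"],
                              columns=[f"s{i}" for i in range(10)])
        out = differential_signatures(scores, self.groups(5, 5))
        assert out.loc["flat", "p"] == 1.0
        assert not bool(out.loc["flat", "flagged"])

    def test_bh_false_flag_control_under_null(self, rng):
        flags = 0
        for _ in range(50):
            scores = pd.DataFrame(
                rng.normal(size=(100, 40)),
                index=[f"set{i}" for i in range(100)],
                columns=[f"s{i}" for i in range(40)],
            )
            out = differential_signatures(scores, self.groups(20, 20))
            flags += out["flagged"].sum()
        # BH at 0.05 over null sets: expected false flags well below 5%
        assert flags / (50 * 100) < 0.05


class TestTmitClassify:
    def quad_expr(self):
        #       s1   s2   s3   s4  : CD274 hi/hi/lo/lo, CD8A hi/lo/lo/hi
        vals = [[9.0, 8.0, 1.0, 2.0],   # CD274 (median 5)
                [9.0, 1.0, 2.0, 8.0],   # CD8A
                [5.0, 5.0, 5.0, 5.0]]
        return expr_from(vals, genes=["CD274", "CD8A", "other"],
                         samples=["s1", "s2", "s3", "s4"])

    def test_four_quadrants(self):
        labels = tmit_classify(self.quad_expr())
        assert list(labels) == ["I", "II", "III", "IV"]

    def test_partition_counts_sum(self):
        labels = tmit_classify(self.quad_expr())
        assert labels.value_counts().sum() == 4

    def test_all_identical_at_cutpoint_class_iii(self):
        expr = expr_from(np.full((3, 4), 2.0), genes=["CD274", "CD8A", "x"])
        labels = tmit_classify(expr)
        assert (labels == "III").all()

    def test_missing_gene_errors(self, rng):
        expr = expr_from(rng.normal(size=(2, 3)), genes=["CD274", "x"])
        with pytest.raises(KeyError, match="CD8A"):
            tmit_classify(expr)

    def test_explicit_cutpoints(self):
        labels = tmit_classify(self.quad_expr(),
                               cutpoint={"CD274": 0.0, "CD8A": 0.0})
        assert (labels == "I").all()


class TestGeneGroupComparison:
    def test_identical_groups_nothing_significant(self, rng):
        half = rng.normal(size=(3, 10))
        expr = expr_from(np.hstack([half, half]))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=expr.sample_ids)
        out = gene_group_comparison(expr, ["g0", "g1"], groups)
        assert (out["stars"] == "").all()

    def test_large_shift_highly_significant(self, rng):
        vals = rng.normal(0, 1, size=(3, 80))
        vals[1, 40:] += 2.0  # 2 SD shift at n = 40/40
        expr = expr_from(vals)
        groups = pd.Series(["a"] * 40 + ["b"] * 40, index=expr.sample_ids)
        out = gene_group_comparison(expr, ["g0", "g1", "g2"], groups)
        assert out.loc["g1", "stars"] == "***"

    def test_bh_identity_for_single_gene(self, rng):
        vals = rng.normal(size=(2, 30))
        expr = expr_from(vals)
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=expr.sample_ids)
        out = gene_group_comparison(expr, ["g0"], groups)
        assert out.loc["g0", "p_adj"] == pytest.approx(out.loc["g0", "p"])

    def test_missing_gene_errors(self, rng):
        expr = expr_from(rng.normal(size=(2, 4)))
        groups = pd.Series(["a", "a", "b", "b"], index=expr.sample_ids)
        with pytest.raises(KeyError, match="ghost"):
            gene_group_comparison(expr, ["ghost"], groups)


class TestScoreRiskCorrelation:
    def test_perfect_correlations(self):
        risk = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0],
                         index=[f"s{i}" for i in range(5)])
        scores = pd.DataFrame(
            {s: [risk[s], -risk[s]] for s in risk.index},
            index=["same", "anti"],
        )
        out = score_risk_correlation(scores, risk)
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)

    def test_constant_score_reported_undefined(self):
        risk = pd.Series(np.arange(5.0), index=[f"s{i}" for i in range(5)])
        scores = pd.DataFrame(np.ones((1, 5)), index=["flat"],
                              columns=risk.index)
        out = score_risk_correlation(scores, risk)
        assert np.isnan(out.loc["flat", "rho"])
        assert out.loc["flat", "note"] == "constant vector"

    def test_too_few_samples_errors(self, rng):
        risk = pd.Series([1.0, 2.0], index=["s0", "s1"])
        scores = pd.DataFrame(rng.normal(size=(1, 2)), index=["x"],
                              columns=risk.index)
        with pytest.raises(ValueError, match="5"):
            score_risk_correlation(scores, risk)

    def test_independent_scores_small_rho(self, rng):
        risk = pd.Series(rng.normal(size=200),
                         index=[f"s{i}" for i in range(200)])
        scores = pd.DataFrame(rng.normal(size=(10, 200)),
                              index=[f"set{i}" for i in range(10)],
                              columns=risk.index)
        out = score_risk_correlation(scores, risk)
        assert (out["rho"].abs() < 0.25).all()
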