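import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import oracles
from pairsig import (
    build_pair_matrix,
    cox_multivariate,
    cox_univariate,
    harrell_c,
    kaplan_meier,
    log_rank,
    optimal_cutoff,
    screen_pairs,
    time_roc,
)
from pairsig.simulate import gene_name

from conftest import clin_from


class TestKaplanMeier:
    def test_all_events_equals_empirical_survival(self):
        curve = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.at(2.5) == pytest.approx(0.5, abs=1e-12)
        # no censoring: S equals the empirical survivor function everywhere
        for t in [0.5, 1, 1.5, 2, 3, 3.9, 4]:
            emp = np.mean(np.array([1, 2, 3, 4]) > t)
            assert curve.at(t) == pytest.approx(emp, abs=1e-12)

    def test_single_censored_subject_flat_one(self):
        curve = kaplan_meier([5.0], [0])
        assert curve.at(10.0) == 1.0
        assert curve.times.size == 0

    def test_hand_computed_product_limit(self):
        # times (1,2,3), events (1,0,1): S(1)=2/3, S(3)=(2/3)*(1-1/1)=0
        curve = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert curve.at(1) == pytest.approx(2 / 3, abs=1e-12)
        assert curve.at(3) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        t = rng.exponential(5, size=8).round(1) + 0.1
        e = rng.integers(0, 2, size=8)
        e[0] = 1
        curve = kaplan_meier(t, e)
        for q in np.linspace(0.1, t.max(), 7):
            assert curve.at(q) == pytest.approx(
                oracles.km_survival(t, e, q), abs=1e-10
            )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = log_rank(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_six_subject_case_matches_formula_oracle(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 1, 1, 0, 1]
        g = ["a", "b", "a", "b", "a", "b"]
        stat, p = log_rank(t, e, g)
        stat_o, p_o = oracles.logrank_two_group(t, e, g)
        assert stat == pytest.approx(stat_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_invariant_to_relabeling_and_time_rescaling(self, rng):
        t = rng.exponential(5, size=30) + 0.1
        e = rng.integers(0, 2, size=30)
        e[:3] = 1
        g = rng.integers(0, 2, size=30)
        stat1, _ = log_rank(t, e, g)
        stat2, _ = log_rank(t * 7.3, e, 1 - g)
        assert stat1 == pytest.approx(stat2, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            log_rank([1, 2], [1, 1], ["a", "a"])


class TestCoxUnivariate:
    def test_constant_covariate_degenerate(self):
        res = cox_univariate([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 0, 1])
        assert res.degenerate

    def test_all_censored_errors(self):
        with pytest.raises(ValueError, match="zero events"):
            cox_univariate([0, 1, 0], [1, 2, 3], [0, 0, 0])

    def test_recovers_planted_log_hazard(self, planted_cohort):
        config, expr, clin = planted_cohort
        pm = build_pair_matrix(expr, [gene_name(0), gene_name(1)])
        res = cox_univariate(pm.values[0], clin.time, clin.event)
        assert not res.degenerate
        assert res.p_value < 0.05
        assert res.log_hr == pytest.approx(1.5, abs=0.5)

    def test_single_covariate_multivariate_reduction(self, rng):
        x = rng.normal(size=50)
        t = rng.exponential(5, size=50) + 0.1
        e = rng.integers(0, 2, size=50)
        e[:5] = 1
        uni = cox_univariate(x, t, e)
        multi = cox_multivariate(pd.DataFrame({"x": x}), t, e)
        assert multi.loc["x", "log_hr"] == pytest.approx(uni.log_hr, abs=1e-8)
        assert multi.loc["x", "p"] == pytest.approx(uni.p_value, abs=1e-8)


class TestCoxMultivariate:
    def test_duplicated_column_collinearity_error(self, rng):
        x = rng.normal(size=40)
        design = pd.DataFrame({"a": x, "b": x})
        t = rng.exponential(5, size=40) + 0.1
        e = np.ones(40, dtype=int)
        with pytest.raises(ValueError, match="collinear.*b"):
            cox_multivariate(design, t, e)

    def test_signature_independent_of_noise_covariates(self, planted_cohort):
        config, expr, clin = planted_cohort
        pm = build_pair_matrix(expr, [gene_name(0), gene_name(1)])
        rng = np.random.default_rng(5)
        design = pd.DataFrame({
            "signature": pm.values[0].astype(float),
            "age": rng.normal(15, 5, size=pm.n_samples),
            "sex": rng.integers(0, 2, size=pm.n_samples).astype(float),
        })
        out = cox_multivariate(design, clin.time, clin.event)
        assert out.loc["signature", "p"] < 0.01
        assert out.loc["age", "p"] > 0.05
        assert out.loc["sex", "p"] > 0.05


class TestScreenPairs:
    def test_alpha_zero_keeps_nothing(self, planted_cohort):
        _, expr, clin = planted_cohort
        pm = build_pair_matrix(expr, expr.gene_ids)
        kept, report = screen_pairs(pm, clin, alpha=0.0)
        assert kept == []
        assert report["kept"].sum() == 0

    def test_planted_pair_kept(self, planted_cohort):
        _, expr, clin = planted_cohort
        pm = build_pair_matrix(expr, expr.gene_ids)
        kept, report = screen_pairs(pm, clin)
        labels = [p.label for p in kept]
        assert f"{gene_name(0)}|{gene_name(1)}" in labels
        assert "p_adj_bh" in report.columns  # transparency column present

    def test_sample_mismatch_errors(self, planted_cohort):
        _, expr, clin = planted_cohort
        pm = build_pair_matrix(expr, expr.gene_ids)
        bad = clin_from([1, 2], [1, 0], samples=["x1", "x2"])
        with pytest.raises(ValueError, match="sample ids"):
            screen_pairs(pm, bad)


class TestHarrellC:
    def test_perfect_concordance(self):
        assert harrell_c([4, 3, 2, 1], [1, 2, 3, 4], [1, 1, 1, 1]) == 1.0

    def test_constant_risk_half(self):
        assert harrell_c([2, 2, 2], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_enumerated_three_subject_case(self):
        # comparable pairs: (t1,t2) discordant, (t1,t3) discordant,
        # (t2,t3) concordant -> 1/3
        assert harrell_c([1, 3, 2], [1, 2, 3], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_matches_enumeration_oracle_with_censoring(self, rng):
        t = rng.permutation(np.arange(1.0, 9.0))
        e = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        r = rng.normal(size=8)
        assert harrell_c(r, t, e) == pytest.approx(
            oracles.harrell_c(r, t, e), abs=1e-10
        )

    def test_antisymmetry_on_tie_free_data(self, rng):
        t = rng.permutation(np.arange(1.0, 21.0))
        r = rng.normal(size=20)
        e = np.ones(20, dtype=int)
        assert harrell_c(r, t, e) + harrell_c(-r, t, e) == pytest.approx(1.0)

    def test_no_events_errors(self):
        with pytest.raises(ValueError):
            harrell_c([1, 2], [1, 2], [0, 0])


class TestTimeROC:
    def test_no_censoring_reduces_to_binary_roc(self, rng):
        t = rng.exponential(5, size=40) + 0.1
        e = np.ones(40, dtype=int)
        r = rng.normal(size=40)
        horizon = float(np.median(t))
        roc = time_roc(r, t, e, horizon)
        y = (t <= horizon).astype(int)
        assert roc.auc == pytest.approx(roc_auc_score(y, r), abs=1e-10)

    def test_perfect_separation_auc_one(self):
        t = [1, 2, 3, 10, 11, 12]
        e = [1, 1, 1, 0, 0, 0]
        r = [5, 6, 7, 1, 2, 3]
        assert time_roc(r, t, e, horizon=5.0).auc == pytest.approx(1.0)

    def test_censored_case_matches_direct_oracle(self):
        t = [1.0, 2.0, 2.5, 4.0, 5.0, 6.0]
        e = [1, 1, 0, 1, 0, 1]
        r = [2.2, 1.9, 0.5, 1.1, 0.3, 0.8]
        roc = time_roc(r, t, e, horizon=4.5)
        thr_o, tpr_o, fpr_o, auc_o = oracles.ipcw_time_roc(r, t, e, 4.5)
        np.testing.assert_allclose(roc.thresholds, thr_o, atol=1e-12)
        np.testing.assert_allclose(roc.tpr, tpr_o, atol=1e-10)
        np.testing.assert_allclose(roc.fpr, fpr_o, atol=1e-10)
        assert roc.auc == pytest.approx(auc_o, abs=1e-10)

    def test_monotone_transform_of_risk_preserves_auc(self, rng):
        t = rng.exponential(5, size=30) + 0.1
        e = rng.integers(0, 2, size=30)
        e[:10] = 1
        r = rng.normal(size=30)
        h = float(np.median(t))
        auc1 = time_roc(r, t, e, h).auc
        auc2 = time_roc(np.exp(2 * r), t, e, h).auc
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_zero_cases_or_controls_error(self):
        with pytest.raises(ValueError, match="no cases"):
            time_roc([1, 2, 3], [5, 6, 7], [0, 0, 1], horizon=5.0)
        with pytest.raises(ValueError):
            time_roc([1, 2, 3], [1, 2, 3], [1, 1, 1], horizon=3.0)

    def test_tpr_fpr_monotone_along_thresholds(self, rng):
        t = rng.exponential(5, size=50) + 0.1
        e = rng.integers(0, 2, size=50)
        e[:10] = 1
        r = rng.normal(size=50)
        roc = time_roc(r, t, e, float(np.median(t)))
        assert (np.diff(roc.tpr) <= 1e-12).all()
        assert (np.diff(roc.fpr) <= 1e-12).all()


class TestOptimalCutoff:
    def test_perfect_separation_smallest_achieving_j1(self):
        roc = time_roc([5, 6, 7, 1, 2, 3], [1, 2, 3, 10, 11, 12],
                       [1, 1, 1, 0, 0, 0], horizon=5.0)
        # smallest threshold with J = 1 is the largest control score
        assert optimal_cutoff(roc) == 3

    def test_flat_j_warns_and_returns_smallest(self):
        from pairsig.survival import TimeROC

        roc = TimeROC(horizon=1.0, thresholds=np.array([0.2, 0.7]),
                      tpr=np.array([0.6, 0.3]), fpr=np.array([0.6, 0.3]),
                      auc=0.5)
        assert optimal_cutoff(roc) == pytest.approx(0.2)

    def test_matches_exhaustive_scan(self, rng):
        t = rng.exponential(5, size=8) + 0.1
        e = np.ones(8, dtype=int)
        r = rng.normal(size=8)
        roc = time_roc(r, t, e, float(np.median(t)))
        assert optimal_cutoff(roc) == pytest.approx(
            oracles.youden_scan(roc.thresholds, roc.tpr, roc.fpr)
        )
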