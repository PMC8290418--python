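import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from nsclc_scmet import prognosis_survival as ps
from nsclc_scmet.io_formats import ClinicalTable
from tests.conftest import make_clinical


def naive_partial_loglik(beta, x, time, event):
    """Direct risk-set enumeration oracle (Breslow ties), 1 covariate."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def logrank_oracle(tA, eA, tB, eB):
    """Event-time tabulation oracle for the two-group log-rank chi-square."""
    times = sorted(set(np.concatenate([tA[eA == 1], tB[eB == 1]])))
    O = E = V = 0.0
    for t in times:
        nA = np.sum(tA >= t)
        nB = np.sum(tB >= t)
        dA = np.sum((tA == t) & (eA == 1))
        dB = np.sum((tB == t) & (eB == 1))
        n, d = nA + nB, dA + dB
        O += dA
        E += d * nA / n
        if n > 1:
            V += d * (nA / n) * (nB / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestCoxFit:
    def test_three_subject_worked_example(self):
        X = pd.DataFrame({"x": [1.0, 0.0, 1.0]}, index=["a", "b", "c"])
        clin = make_clinical([1, 2, 3], [1, 1, 1], prefix="")
        clin.table.index = pd.Index(["a", "b", "c"], name="sample_id")
        fit = ps.cox_fit(X, clin)
        assert fit.coefficients[0] == pytest.approx(-np.log(2) / 2, abs=1e-4)
        assert fit.converged

    @pytest.mark.parametrize("seed", range(6))
    def test_grid_search_oracle_small_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        x = rng.standard_normal(n)
        time = np.round(rng.exponential(10, n), 3)  # distinct with prob ~1
        event = np.ones(n, dtype=int)
        clin = make_clinical(time, event)
        X = pd.DataFrame({"x": x}, index=clin.sample_ids)
        fit = ps.cox_fit(X, clin)
        res = optimize.minimize_scalar(
            lambda b: -naive_partial_loglik(b, x, time, event), bounds=(-8, 8),
            method="bounded", options={"xatol": 1e-8})
        assert fit.coefficients[0] == pytest.approx(res.x, abs=1e-4)

    def test_duplicated_dataset_same_beta_breslow(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.standard_normal(n)
        time = rng.exponential(5, n)
        event = rng.integers(0, 2, n)
        event[0] = 1
        clin = make_clinical(time, event)
        X = pd.DataFrame({"x": x}, index=clin.sample_ids)
        fit1 = ps.cox_fit(X, clin, "breslow")
        clin2 = make_clinical(np.tile(time, 2), np.tile(event, 2), prefix="d")
        X2 = pd.DataFrame({"x": np.tile(x, 2)}, index=clin2.sample_ids)
        fit2 = ps.cox_fit(X2, clin2, "breslow")
        assert fit2.coefficients[0] == pytest.approx(fit1.coefficients[0], abs=1e-6)

    def test_matches_lifelines_multivariate(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(2)
        n = 120
        X = rng.standard_normal((n, 3))
        time = rng.exponential(100 * np.exp(-X[:, 0] * 0.5), n)
        event = (rng.random(n) < 0.8).astype(int)
        clin = make_clinical(time, event)
        Xdf = pd.DataFrame(X, columns=list("abc"), index=clin.sample_ids)
        fit = ps.cox_fit(Xdf, clin, "breslow")
        df = Xdf.copy()
        df["time"], df["event"] = time, event
        ll = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(fit.coefficients, ll.params_.to_numpy(), atol=1e-4)
        np.testing.assert_allclose(fit.standard_errors,
                                   ll.standard_errors_.to_numpy(), atol=1e-4)

    def test_efron_differs_under_heavy_ties(self):
        time = np.array([1, 1, 1, 2, 2, 3.0])
        event = np.array([1, 1, 0, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.5, -0.5, 0.0])
        clin = make_clinical(time, event)
        X = pd.DataFrame({"x": x}, index=clin.sample_ids)
        b_bres = ps.cox_fit(X, clin, "breslow").coefficients[0]
        b_efr = ps.cox_fit(X, clin, "efron").coefficients[0]
        assert b_bres != pytest.approx(b_efr, abs=1e-6)

    def test_null_covariate_p_not_small(self):
        rng = np.random.default_rng(3)
        n = 500
        clin = make_clinical(rng.exponential(10, n), np.ones(n, dtype=int))
        X = pd.DataFrame({"x": rng.standard_normal(n)}, index=clin.sample_ids)
        fit = ps.cox_fit(X, clin)
        assert abs(fit.coefficients[0]) < 0.2

    def test_constant_covariate_is_error(self):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0]}, index=clin.sample_ids)
        with pytest.raises(ValueError, match="constant"):
            ps.cox_fit(X, clin)


class TestLassoScreen:
    def test_huge_lambda_selects_nothing(self, surv_sim):
        expr, clin, _ = surv_sim
        sel, _ = ps.lasso_screen(expr, clin, lambda_grid=np.array([1e4]),
                                 cv_folds=3, seed=0)
        assert sel == []

    def test_zero_lambda_selects_all(self, surv_sim):
        expr, clin, _ = surv_sim
        sel, _ = ps.lasso_screen(expr, clin, lambda_grid=np.array([0.0]))
        assert sel == list(expr.columns)

    def test_no_events_is_error(self):
        clin = make_clinical([1, 2, 3, 4], [0, 0, 0, 0])
        X = pd.DataFrame(np.random.default_rng(0).random((4, 2)),
                         index=clin.sample_ids, columns=["a", "b"])
        with pytest.raises(ValueError, match="no events"):
            ps.lasso_screen(X, clin, cv_folds=2)


class TestRiskModel:
    def test_select_significant_bounds(self):
        fit = ps.CoxFit(["a", "b"], np.array([1.0, 0.1]), np.array([0.1, 0.1]),
                        np.array([10.0, 1.0]), np.array([1e-4, 0.3]), -1.0, True,
                        "breslow", 3)
        assert ps.select_significant(fit, alpha=0.05) == ["a"]
        assert ps.select_significant(fit, alpha=1.0) == ["a", "b"]
        assert ps.select_significant(fit, alpha=1e-8) == []

    def test_risk_score_linear(self):
        model = ps.RiskModel(["MAP3K8", "HERPUD1", "GAPDH", "DNAJB4"],
                             np.array([-0.197, -0.261, 0.185, 0.191]))
        X = pd.DataFrame([[0, 0, 0, 0], [1, 1, 1, 1], [2, 0, 1, 0.0]],
                         columns=model.genes)
        s = ps.risk_score(model, X)
        assert s.iloc[0] == 0.0
        assert s.iloc[1] == pytest.approx(-0.082, abs=1e-12)
        x, y = X.iloc[1], X.iloc[2]
        assert ps.risk_score(model, pd.DataFrame([x + y]))[0] == \
            pytest.approx(s.iloc[1] + s.iloc[2])

    def test_missing_gene_named_in_error(self):
        model = ps.RiskModel(["A"], np.array([1.0]))
        with pytest.raises(KeyError, match="A"):
            ps.risk_score(model, pd.DataFrame({"B": [1.0]}))

    def test_median_split_rules(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert ps.median_split(s).tolist() == ["low", "low", "high", "high"]
        odd = pd.Series([1.0, 2.0, 3.0])
        assert ps.median_split(odd).tolist() == ["low", "low", "high"]
        shifted = ps.median_split(s + 100.0)
        assert shifted.tolist() == ps.median_split(s).tolist()


class TestKMAndLogrank:
    def test_product_limit_no_censoring(self):
        km = ps.km_estimate(make_clinical([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_product_limit_with_censoring(self):
        km = ps.km_estimate(make_clinical([1, 2, 3], [0, 1, 1]))
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_no_events_flat_curve(self):
        km = ps.km_estimate(make_clinical([1, 2], [0, 0]))
        assert km.event_times.size == 0

    def test_identical_groups_chi2_zero(self):
        a = make_clinical([1, 2, 3], [1, 1, 0], "a")
        b = make_clinical([1, 2, 3], [1, 1, 0], "b")
        chi2, p = ps.logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_worked_example_and_symmetry(self):
        a = make_clinical([1, 2], [1, 1], "a")
        b = make_clinical([3, 4], [1, 1], "b")
        chi2, p = ps.logrank_test(a, b)
        assert chi2 == pytest.approx(49 / 17, abs=1e-3)
        chi2_swapped, p_swapped = ps.logrank_test(b, a)
        assert chi2_swapped == pytest.approx(chi2, abs=1e-10)
        assert p_swapped == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_tabulation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nA, nB = int(rng.integers(4, 11)), int(rng.integers(4, 11))
        tA = rng.integers(1, 8, nA).astype(float)
        tB = rng.integers(1, 8, nB).astype(float)
        eA = rng.integers(0, 2, nA)
        eB = rng.integers(0, 2, nB)
        eA[0] = eB[0] = 1
        chi2, _ = ps.logrank_test(make_clinical(tA, eA, "a"), make_clinical(tB, eB, "b"))
        assert chi2 == pytest.approx(logrank_oracle(tA, eA, tB, eB), abs=1e-10)


class TestAuc:
    def test_perfect_ranking_gives_one(self):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        scores = pd.Series([3.0, 2.0, 1.0], index=clin.sample_ids)
        assert ps.time_dependent_auc(scores, clin, 1.5)[0] == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        n = 60
        clin = make_clinical(rng.exponential(10, n), np.ones(n, dtype=int))
        scores = pd.Series(rng.standard_normal(n), index=clin.sample_ids)
        t = float(np.median(clin.time))
        a = ps.time_dependent_auc(scores, clin, t)[0]
        b = ps.time_dependent_auc(np.exp(scores * 3), clin, t)[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 2000
        clin = make_clinical(rng.exponential(10, n), np.ones(n, dtype=int))
        scores = pd.Series(rng.standard_normal(n), index=clin.sample_ids)
        auc = ps.time_dependent_auc(scores, clin, float(np.median(clin.time)))[0]
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_undefined_without_cases(self):
        clin = make_clinical([5.0, 6.0], [1, 1])
        scores = pd.Series([1.0, 2.0], index=clin.sample_ids)
        with pytest.raises(ValueError, match="cases"):
            ps.time_dependent_auc(scores, clin, 1.0)


class TestSurvivalProbability:
    def test_zero_beta_gives_marginal_curve_for_all_profiles(self):
        rng = np.random.default_rng(6)
        n = 50
        clin = make_clinical(rng.exponential(10, n), np.ones(n, dtype=int))
        X = pd.DataFrame({"x": rng.standard_normal(n)}, index=clin.sample_ids)
        fit = ps.cox_fit(X, clin)
        fit.coefficients = np.array([0.0])
        fit._eta = np.zeros(n)
        t = float(np.median(clin.time))
        sp = ps.survival_probability(fit, X, (t,))
        assert sp.iloc[:, 0].nunique() == 1  # same survival whatever x

    def test_monotone_in_linear_predictor(self):
        rng = np.random.default_rng(7)
        n = 200
        x = rng.standard_normal(n)
        time = rng.exponential(np.exp(-x), n)
        clin = make_clinical(time, np.ones(n, dtype=int))
        X = pd.DataFrame({"x": x}, index=clin.sample_ids)
        fit = ps.cox_fit(X, clin)
        grid = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        sp = ps.survival_probability(fit, grid, (float(np.median(time)),))
        assert sp.iloc[0, 0] > sp.iloc[1, 0] > sp.iloc[2, 0]

    def test_horizon_beyond_follow_up_carried_forward(self, caplog):
        clin = make_clinical([1, 2, 3], [1, 1, 1])
        X = pd.DataFrame({"x": [0.5, -0.5, 0.1]}, index=clin.sample_ids)
        fit = ps.cox_fit(X, clin)
        sp = ps.survival_probability(fit, X, (3.0, 100.0))
        np.testing.assert_allclose(sp["S_3"], sp["S_100"])
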