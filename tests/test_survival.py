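"""Kaplan-Meier, log-rank and Cox regression against hand computation,
brute-force accumulation, and lifelines as the independent oracle."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from tlsig import (ClinicalTable, CollinearityError, ValidationError,
                   cox_fit, cox_score_test, km_estimate, logrank_test,
                   stratify_by_quartile, survival_screen)


def clinical_of(time, event, ids=None):
    ids = ids or [f"s{i}" for i in range(len(time))]
    return ClinicalTable(
        pd.DataFrame({"time": time, "event": event},
                     index=pd.Index(ids, name="sample_id"))
    )


def brute_force_logrank_2group(time, event, is_b):
    """Independent O/E/V accumulation over event times for two groups."""
    O = E = V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n_b = (at_risk & is_b).sum()
        d = ((time == t) & (event == 1)).sum()
        d_b = ((time == t) & (event == 1) & is_b).sum()
        O += d_b
        E += d * n_b / n
        if n > 1:
            V += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestKaplanMeier:
    def test_hand_product_limit(self, five_subject_clinical):
        km = km_estimate(five_subject_clinical)
        tab = km.groups["all"]
        np.testing.assert_allclose(tab["time"], [2, 3, 5])
        np.testing.assert_allclose(tab["survival"], [0.75, 0.5, 0.0])
        assert km.survival_at("all", 1.5) == 1.0

    def test_all_censored_flat_curve(self):
        with pytest.warns(UserWarning, match="no events"):
            km = km_estimate(clinical_of([1, 2, 3.0], [0, 0, 0]))
        assert km.groups["all"].empty
        assert km.survival_at("all", 99) == 1.0

    def test_simultaneous_events_drop_to_zero(self):
        km = km_estimate(clinical_of([2.0] * 6, [1] * 6))
        assert km.survival_at("all", 2.0) == 0.0

    def test_no_censoring_matches_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 50)
        km = km_estimate(clinical_of(t, np.ones(50, int)))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km.survival_at("all", q) == pytest.approx((t > q).mean())


class TestLogRank:
    def test_duplicated_groups_give_zero_statistic(self):
        t = [1.0, 2, 3, 4, 5] * 2
        e = [1, 0, 1, 1, 0] * 2
        g = pd.Series(["A"] * 5 + ["B"] * 5,
                      index=[f"s{i}" for i in range(10)])
        res = logrank_test(clinical_of(t, e), g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_accumulation(self):
        time = np.array([1.0, 2, 3, 4, 5, 6])
        event = np.ones(6, int)
        is_b = np.array([False] * 3 + [True] * 3)
        g = pd.Series(np.where(is_b, "B", "A"),
                      index=[f"s{i}" for i in range(6)])
        res = logrank_test(clinical_of(time, event), g)
        expected = brute_force_logrank_2group(time, event, is_b)
        assert res.chi2 == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_lifelines_k_groups(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        t = rng.exponential(1, n)
        e = rng.integers(0, 2, n)
        e[:3] = 1
        g = rng.choice(["a", "b", "c"], n)
        res = logrank_test(clinical_of(t, e),
                           pd.Series(g, index=[f"s{i}" for i in range(n)]))
        ref = multivariate_logrank_test(t, g, e)
        assert res.chi2 == pytest.approx(ref.test_statistic, abs=1e-9)
        assert res.df == 2
        assert res.observed.sum() == pytest.approx(res.expected.sum(),
                                                   abs=1e-9)

    def test_time_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(1, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = pd.Series(rng.choice(["A", "B"], 30),
                      index=[f"s{i}" for i in range(30)])
        r1 = logrank_test(clinical_of(t, e), g)
        r2 = logrank_test(clinical_of(np.exp(t), e), g)  # monotone relabel
        assert r1.chi2 == pytest.approx(r2.chi2, abs=1e-12)


class TestCox:
    def test_symmetric_arms_give_zero_coefficient(self):
        t = [1.0, 2, 3, 4, 5] * 2
        e = [1, 0, 1, 1, 1] * 2
        clin = clinical_of(t, e)
        x = pd.DataFrame({"arm": [0.0] * 5 + [1.0] * 5},
                         index=clin.data.index)
        fit = cox_fit(clin, x)
        assert abs(fit.beta[0]) < 1e-6
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-5)

    def test_matches_lifelines_under_efron_ties(self, tied_clinical_20):
        clin, cov = tied_clinical_20
        fit = cox_fit(clin, cov, ties="efron")
        df = clin.data.assign(x=cov["x"])
        ref = CoxPHFitter().fit(df, "time", "event")
        assert fit.beta[0] == pytest.approx(ref.params_["x"], abs=1e-4)
        assert fit.se[0] == pytest.approx(ref.standard_errors_["x"],
                                          abs=1e-4)
        assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-4)
        assert fit.converged

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        t = rng.exponential(np.exp(-(-2.5 + 0.7 * x)))
        clin = clinical_of(t, np.ones(500, int))
        fit = cox_fit(clin, pd.DataFrame({"x": x}, index=clin.data.index))
        assert 0.55 <= fit.beta[0] <= 0.85

    def test_shift_and_scale_equivariance(self, tied_clinical_20):
        clin, cov = tied_clinical_20
        base = cox_fit(clin, cov)
        shifted = cox_fit(clin, cov + 100.0)
        scaled = cox_fit(clin, cov * 3.0)
        assert shifted.beta[0] == pytest.approx(base.beta[0], abs=1e-8)
        assert scaled.beta[0] == pytest.approx(base.beta[0] / 3.0, abs=1e-8)

    def test_sign_agrees_with_km_ordering(self):
        rng = np.random.default_rng(9)
        arm = np.repeat([0.0, 1.0], 50)
        t = rng.exponential(np.exp(-arm))  # arm 1 has lower hazard
        clin = clinical_of(t, np.ones(100, int))
        fit = cox_fit(clin, pd.DataFrame({"arm": arm},
                                         index=clin.data.index))
        km = km_estimate(clin, pd.Series(np.where(arm == 1, "hi", "lo"),
                                         index=clin.data.index))
        t_med = np.median(t)
        below = km.survival_at("lo", t_med) < km.survival_at("hi", t_med)
        assert (fit.beta[0] < 0) == below

    def test_constant_covariate_dropped_and_fit_unchanged(self,
                                                          tied_clinical_20):
        clin, cov = tied_clinical_20
        with_const = cov.assign(const=1.0)
        with pytest.warns(UserWarning, match="constant"):
            fit = cox_fit(clin, with_const)
        ref = cox_fit(clin, cov)
        assert fit.names == ["x"]
        assert fit.dropped == ["const"]
        assert fit.beta[0] == pytest.approx(ref.beta[0], abs=1e-10)

    def test_collinear_covariates_rejected_by_name(self, tied_clinical_20):
        clin, cov = tied_clinical_20
        design = cov.assign(x2=cov["x"] * 2.0)
        with pytest.raises(CollinearityError, match="x2"):
            cox_fit(clin, design)

    def test_separation_flagged_not_silent(self):
        # covariate perfectly ordered with event times: monotone likelihood
        t = np.arange(1.0, 21.0)
        clin = clinical_of(t, np.ones(20, int))
        x = pd.DataFrame({"x": t}, index=clin.data.index)
        with pytest.warns(UserWarning, match="converge"):
            fit = cox_fit(clin, x, max_iter=5)
        assert not fit.converged

    def test_no_events_rejected(self):
        clin = clinical_of([1.0, 2.0], [0, 0])
        with pytest.raises(ValidationError):
            cox_fit(clin, pd.DataFrame({"x": [0.0, 1.0]},
                                       index=clin.data.index))


class TestScoreTestEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_squared_score_statistic_equals_logrank(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 30
        t = rng.exponential(1, n)  # continuous: no ties
        e = rng.integers(0, 2, n)
        e[:2] = 1
        grp = rng.integers(0, 2, n)
        clin = clinical_of(t, e)
        stat, _ = cox_score_test(
            clin, pd.DataFrame({"g": grp.astype(float)},
                               index=clin.data.index))
        lr = logrank_test(clin, pd.Series(np.where(grp == 1, "B", "A"),
                                          index=clin.data.index))
        assert stat == pytest.approx(lr.chi2, abs=1e-6)


class TestSurvivalScreen:
    def test_single_binary_covariate_modes_agree(self):
        rng = np.random.default_rng(2)
        n = 60
        t = rng.exponential(1, n)
        clin = clinical_of(t, np.ones(n, int))
        cov = pd.DataFrame({"grp": rng.choice(["a", "b"], n)},
                           index=clin.data.index)
        out = survival_screen(clin, cov, mode="both")
        uni = out[out["mode"] == "univariate"].iloc[0]
        multi = out[out["mode"] == "multivariate"].iloc[0]
        assert uni["coef"] == pytest.approx(multi["coef"], abs=1e-10)

    def test_protective_tls_class_has_hr_below_one(self, default_cohort,
                                                   default_scores):
        strata = stratify_by_quartile(default_scores.series("TLS"),
                                      mode="two_class_q3")
        cov = pd.DataFrame({
            "tls": strata.labels,
            "age": default_cohort.clinical.data["age"],
            "gender": default_cohort.clinical.data["gender"],
        })
        out = survival_screen(default_cohort.clinical, cov, mode="both",
                              reference={"tls": "low"})
        hi = out[out["covariate"] == "tls[hi]"]
        assert len(hi) == 2  # one row per mode
        assert (hi["hr"] < 1).all()
        assert (hi["p"] < 0.05).all()
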