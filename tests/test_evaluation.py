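import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from irgp.data_io import ClinicalTable
from irgp.evaluation import binary_roc, cox_with_covariates, km_logrank, td_auc
from irgp.screening import univariate_cox
from irgp.signature import assign_groups


def _clin(time, event, unit="months", **covariates):
    idx = pd.Index([f"s{i}" for i in range(len(time))], name="sample_id")
    df = pd.DataFrame({"time": time, "event": event, **covariates}, index=idx)
    return ClinicalTable(df, unit)


def _assign(groups):
    idx = pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id")
    return pd.DataFrame(
        {"irgpi": np.where(np.asarray(groups) == "high", 1.0, -1.0), "group": groups},
        index=idx,
    )


class TestKMLogrank:
    def test_product_limit_hand_computation(self):
        # group a: events at 1,2,3 -> survival 2/3, 1/3, 0; group b censored-only
        clin = _clin([1, 2, 3, 5, 6], [1, 1, 1, 0, 0])
        assign = _assign(["a", "a", "a", "b", "b"]).assign(group=["a", "a", "a", "b", "b"])
        curves, chi2, p = km_logrank(assign, clin)
        np.testing.assert_allclose(curves["a"].survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert (curves["b"].survival == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        time = rng.exponential(10, size=40)
        clin = _clin(time, np.ones(40, dtype=int))
        groups = ["a"] * 20 + ["b"] * 20
        curves, _, _ = km_logrank(_assign(groups), clin)
        t_a = np.sort(time[:20])
        emp = 1.0 - np.arange(1, 21) / 20
        np.testing.assert_allclose(curves["a"].survival, emp, atol=1e-12)

    def test_planted_strong_effect_significant(self, planted_cohort):
        cohort, _, _ = planted_cohort
        eta = cohort.truth["linear_predictor"]
        scores = pd.Series(eta, index=cohort.clinical.sample_ids)
        assign = assign_groups(scores, float(np.median(eta)))
        _, _, p = km_logrank(assign, cohort.clinical)
        assert p < 0.001

    def test_single_group_errors(self):
        clin = _clin([1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError, match="both risk groups"):
            km_logrank(_assign(["a", "a", "a"]), clin)

    def test_at_risk_counts_non_increasing(self, planted_cohort):
        cohort, _, _ = planted_cohort
        eta = cohort.truth["linear_predictor"]
        scores = pd.Series(eta, index=cohort.clinical.sample_ids)
        assign = assign_groups(scores, float(np.median(eta)))
        curves, _, _ = km_logrank(assign, cohort.clinical)
        for curve in curves.values():
            assert (np.diff(curve.at_risk) <= 0).all()


class TestTdAuc:
    def test_perfect_ordering_no_censoring(self):
        n = 40
        scores = pd.Series(np.linspace(1, 0, n), index=[f"s{i}" for i in range(n)])
        time = np.linspace(1.0, 200.0, n)  # high score = early death
        clin = _clin(time, np.ones(n, dtype=int))
        aucs = td_auc(scores, clin, [1.0, 3.0, 5.0])
        assert all(a == pytest.approx(1.0) for a in aucs.values())

    def test_agrees_with_sksurv_ipcw_estimator(self):
        rng = np.random.default_rng(21)
        n = 200
        scores = rng.normal(size=n)
        time = rng.exponential(30, size=n) * np.exp(-0.7 * scores)
        event = (rng.uniform(size=n) < 0.7).astype(int)
        clin = _clin(time, event)
        s = pd.Series(scores, index=clin.sample_ids)
        mine = td_auc(s, clin, [1.0])
        y = Surv.from_arrays(event=event.astype(bool), time=time)
        theirs, _ = cumulative_dynamic_auc(y, y, scores, [12.0])
        assert mine[1.0] == pytest.approx(float(theirs[0]), abs=1e-6)

    def test_matches_brute_force_weighted_concordance(self):
        rng = np.random.default_rng(22)
        n = 60
        scores = rng.normal(size=n)
        time = rng.exponential(25, size=n)
        event = (rng.uniform(size=n) < 0.6).astype(int)
        clin = _clin(time, event)
        horizon = 12.0
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        kmf.fit(time, 1 - event)
        case = (time <= horizon) & (event == 1)
        ctrl = time > horizon
        w_case = 1.0 / kmf.survival_function_at_times(time[case] - 1e-9).to_numpy()
        num = den = 0.0
        for sc, wc in zip(scores[case], w_case):
            for su in scores[ctrl]:
                num += wc * ((sc > su) + 0.5 * (sc == su))
                den += wc
        expected = num / den
        mine = td_auc(pd.Series(scores, index=clin.sample_ids), clin, [1.0])
        assert mine[1.0] == pytest.approx(expected, abs=1e-9)


class TestCoxWithCovariates:
    def test_single_binary_covariate_reproduces_univariate(self, planted_cohort):
        cohort, _, _ = planted_cohort
        z = cohort.truth["indicators"][0]
        scores = pd.Series(z, index=cohort.clinical.sample_ids)
        assign = assign_groups(scores, 0.5)
        fit = cox_with_covariates(assign, cohort.clinical, [])
        hr, lo, hi, p = univariate_cox(z, cohort.clinical)
        row = fit.table.iloc[0]
        assert row["hazard_ratio"] == pytest.approx(hr, rel=1e-6)
        assert row["p_value"] == pytest.approx(p, rel=1e-6)

    def test_noise_covariate_leaves_hr_stable(self):
        rng = np.random.default_rng(31)
        n = 400
        z = rng.integers(0, 2, size=n).astype(float)
        time = rng.exponential(1 / (0.05 * np.exp(1.0 * z)))
        event = np.ones(n, dtype=int)
        noise = rng.normal(size=n)
        clin = _clin(time, event, noise=noise)
        assign = assign_groups(pd.Series(z, index=clin.sample_ids), 0.5)
        uni = cox_with_covariates(assign, clin, [])
        multi = cox_with_covariates(assign, clin, ["noise"])
        hr_u = uni.table.loc["riskGroup", "hazard_ratio"]
        hr_m = multi.table.loc["riskGroup", "hazard_ratio"]
        assert abs(hr_m - hr_u) / hr_u < 0.10

    def test_confounder_attenuates_hr(self):
        rng = np.random.default_rng(32)
        n = 500
        confounder = rng.normal(size=n)
        z = (confounder + rng.normal(scale=0.8, size=n) > 0).astype(float)
        time = rng.exponential(1 / (0.05 * np.exp(0.5 * z + 0.8 * confounder)))
        clin = _clin(time, np.ones(n, dtype=int), age=confounder)
        assign = assign_groups(pd.Series(z, index=clin.sample_ids), 0.5)
        uni = cox_with_covariates(assign, clin, [])
        multi = cox_with_covariates(assign, clin, ["age"])
        assert multi.table.loc["riskGroup", "hazard_ratio"] < uni.table.loc["riskGroup", "hazard_ratio"]

    def test_duplicated_covariate_errors(self):
        rng = np.random.default_rng(33)
        n = 50
        age = rng.normal(60, 8, size=n)
        clin = _clin(rng.exponential(10, size=n), np.ones(n, dtype=int), age=age, age2=age)
        assign = _assign(["high", "low"] * 25)
        with pytest.raises(ValueError, match="collinear"):
            cox_with_covariates(assign, clin, ["age", "age2"])

    def test_stage_ordinal_and_categorical_gender(self):
        rng = np.random.default_rng(34)
        n = 120
        stage = rng.choice(["I", "II", "III", "IV"], size=n)
        gender = rng.choice(["female", "male"], size=n)
        time = rng.exponential(10, size=n)
        clin = _clin(time, np.ones(n, dtype=int), stage=stage, gender=gender)
        assign = _assign(rng.choice(["high", "low"], size=n))
        fit = cox_with_covariates(assign, clin, ["stage", "gender"])
        assert "stage" in fit.table.index
        assert "gender[male]" in fit.table.index

    def test_continuous_score_mode(self, planted_cohort):
        cohort, _, _ = planted_cohort
        eta = cohort.truth["linear_predictor"]
        scores = pd.Series(eta, index=cohort.clinical.sample_ids)
        fit = cox_with_covariates(scores, cohort.clinical, [], use_score=True)
        assert fit.table.loc["riskScore", "hazard_ratio"] > 1.0


class TestBinaryRoc:
    def test_labels_from_score_median_split(self):
        rng = np.random.default_rng(41)
        scores = rng.normal(size=200)
        labels = (scores > np.median(scores)).astype(int)
        assert binary_roc(scores, labels) == pytest.approx(1.0)

    def test_null_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert 0.47 <= binary_roc(scores, labels) <= 0.53

    def test_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(43)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        n1, n0 = labels.sum(), (1 - labels).sum()
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert binary_roc(scores, labels) == pytest.approx(u / (n1 * n0))

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            binary_roc(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(st.integers(0, 2**31 - 1))
    def test_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        assert binary_roc(-scores, labels) == pytest.approx(1 - binary_roc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(44)
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        assert binary_roc(np.exp(scores), labels) == pytest.approx(binary_roc(scores, labels))
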