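import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cmrquant import (
    EchoRecord,
    ancova_age_adjust,
    classify_subject,
    correlations,
    generate_cohort,
    one_way_anova,
    roc_youden,
    run_cohort_analysis,
)

# printed group-mean echo profiles (healthy / HFpEF / HFrEF)
PROFILE_HEALTHY = EchoRecord(ef_pct=73.96, e_a=1.26, ep_ap=1.16, septal_ep=9.50, e_ep=8.04)
PROFILE_HFPEF = EchoRecord(ef_pct=76.64, e_a=0.69, ep_ap=0.77, septal_ep=4.78, e_ep=11.49)
PROFILE_HFREF = EchoRecord(ef_pct=47.99, e_a=0.82, ep_ap=0.67, septal_ep=5.02, e_ep=10.1)


class TestClassification:
    @pytest.mark.parametrize(
        "record,expected",
        [(PROFILE_HEALTHY, "healthy"), (PROFILE_HFPEF, "HFpEF"), (PROFILE_HFREF, "HFrEF")],
    )
    def test_group_mean_profiles(self, record, expected):
        assert classify_subject(record) == expected

    def test_reduced_ef_dominates_diastolic_criteria(self):
        rec = EchoRecord(ef_pct=60.0, e_a=0.5, ep_ap=0.5, septal_ep=4.0, e_ep=12.0)
        assert classify_subject(rec) == "HFrEF"

    def test_exactly_two_criteria_needed_for_hfpef(self):
        # one criterion only (septal E' low): healthy
        one = EchoRecord(ef_pct=70.0, e_a=1.2, ep_ap=1.1, septal_ep=6.0, e_ep=9.0)
        assert classify_subject(one) == "healthy"
        # two criteria (septal E' low + E/E' high): HFpEF
        two = EchoRecord(ef_pct=70.0, e_a=1.2, ep_ap=1.1, septal_ep=6.0, e_ep=10.5)
        assert classify_subject(two) == "HFpEF"

    def test_high_ratio_branch_of_criterion_one(self):
        rec = EchoRecord(ef_pct=70.0, e_a=3.5, ep_ap=1.1, septal_ep=6.0, e_ep=9.0)
        assert classify_subject(rec) == "HFpEF"  # E/A > 3 plus low septal E'

    def test_missing_field_rejected(self):
        with pytest.raises(ValueError):
            EchoRecord(ef_pct=float("nan"), e_a=1.0, ep_ap=1.0, septal_ep=8.0, e_ep=9.0)


class TestAnova:
    def test_identical_constant_groups(self):
        f, p = one_way_anova([1.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert f == 0.0 and p == 1.0

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        f, p = one_way_anova(np.r_[x, y], ["a"] * 12 + ["b"] * 9)
        t = sps.ttest_ind(x, y)  # pooled-variance
        assert f == pytest.approx(t.statistic**2, rel=1e-12)
        assert p == pytest.approx(t.pvalue, rel=1e-12)

    def test_three_group_hand_oracle(self):
        vals = np.array([3.1, 2.9, 3.4, 4.0, 4.2, 4.4, 5.5, 5.1, 5.3, 5.0])
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 4)
        # explicit sums-of-squares oracle
        grand = vals.mean()
        ssb = sum(
            (vals[labels == g]).size * ((vals[labels == g]).mean() - grand) ** 2 for g in "abc"
        )
        ssw = sum(((vals[labels == g] - vals[labels == g].mean()) ** 2).sum() for g in "abc")
        f_oracle = (ssb / 2) / (ssw / 7)
        f, p = one_way_anova(vals, labels)
        assert f == pytest.approx(f_oracle, abs=1e-12)
        # independent route: scipy's implementation
        f_sp, p_sp = sps.f_oneway(*(vals[labels == g] for g in "abc"))
        assert f == pytest.approx(f_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-12)

    def test_shift_and_scale_behaviour(self):
        vals = np.array([1.0, 2, 3, 7, 8, 9.5])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        f0, _ = one_way_anova(vals, labels)
        f_shift, _ = one_way_anova(vals + 100, labels)
        f_scale, _ = one_way_anova(vals * 3.7, labels)
        assert f_shift == pytest.approx(f0, rel=1e-12)
        assert f_scale == pytest.approx(f0, rel=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2, 3], ["a", "a", "b"])


class TestAncova:
    def _fixed_dataset(self):
        rng = np.random.default_rng(3)
        age = np.r_[rng.uniform(8, 12, 8), rng.uniform(15, 22, 8)]
        group = np.array(["a"] * 8 + ["b"] * 8)
        value = 20 + 0.3 * age + np.where(group == "b", 4.0, 0.0) + rng.normal(0, 0.5, 16)
        return value, group, age

    def test_coefficients_match_normal_equations(self):
        value, group, age = self._fixed_dataset()
        res = ancova_age_adjust(value, group, age)
        # oracle: X = [1, I(b), age], beta = (X'X)^-1 X'y
        x = np.column_stack([np.ones(16), (group == "b").astype(float), age])
        beta = np.linalg.solve(x.T @ x, x.T @ value)
        mean_age = age.mean()
        assert res.adjusted_means["a"] == pytest.approx(beta[0] + beta[2] * mean_age, abs=1e-10)
        assert res.adjusted_means["b"] == pytest.approx(beta[0] + beta[1] + beta[2] * mean_age, abs=1e-10)
        assert res.covariate_coef == pytest.approx(beta[2], abs=1e-10)
        # extra-sum-of-squares F oracle
        resid_full = value - x @ beta
        x0 = np.column_stack([np.ones(16), age])
        beta0 = np.linalg.solve(x0.T @ x0, x0.T @ value)
        resid_red = value - x0 @ beta0
        sse_full, sse_red = (resid_full**2).sum(), (resid_red**2).sum()
        f_oracle = ((sse_red - sse_full) / 1) / (sse_full / (16 - 3))
        assert res.f_group == pytest.approx(f_oracle, rel=1e-10)
        assert res.p_group == pytest.approx(float(sps.f.sf(f_oracle, 1, 13)), rel=1e-10)

    def test_orthogonal_covariate_leaves_means_alone(self):
        rng = np.random.default_rng(5)
        group = np.array(["a"] * 50 + ["b"] * 50)
        age = np.tile(rng.uniform(5, 20, 50), 2)  # identical age distribution per group
        value = np.where(group == "b", 25.0, 20.0) + rng.normal(0, 1.0, 100)
        res = ancova_age_adjust(value, group, age)
        raw_a = value[group == "a"].mean()
        raw_b = value[group == "b"].mean()
        assert res.adjusted_means["a"] == pytest.approx(raw_a, abs=0.5)
        assert res.adjusted_means["b"] == pytest.approx(raw_b, abs=0.5)

    def test_pure_age_confound_removed(self):
        rng = np.random.default_rng(8)
        age = np.r_[rng.uniform(8, 12, 10), rng.uniform(16, 20, 10)]
        group = np.array(["a"] * 10 + ["b"] * 10)
        value = 2.0 * age + rng.normal(0, 0.02, 20)  # groups differ only through age
        res = ancova_age_adjust(value, group, age)
        assert res.p_group > 0.2

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            ancova_age_adjust([1.0, 2, 3, 4], ["a", "a", "b", "b"], [5.0, 5, 5, 5])


class TestCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = correlations(x, x.copy())
        assert res["pearson"][0] == pytest.approx(1.0)

    def test_constant_covariate_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = correlations(x, y, covariate=np.full(20, 3.0))
        assert res["partial"] == res["pearson"]

    def test_partial_matches_residual_oracle_and_pingouin(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=30)
        x = 0.5 * z + rng.normal(size=30)
        y = -0.7 * z + rng.normal(size=30)
        res = correlations(x, y, covariate=z)
        # residual-method oracle via polyfit
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        r_oracle = np.corrcoef(rx, ry)[0, 1]
        assert res["partial"][0] == pytest.approx(r_oracle, abs=1e-12)
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        tbl = pingouin.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z")
        assert res["partial"][0] == pytest.approx(float(tbl["r"].iloc[0]), abs=1e-10)
        assert res["partial"][1] == pytest.approx(float(tbl["p_val"].iloc[0]), abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlations(np.ones(10), np.arange(10.0))


def auc_pair_oracle(scores, labels):
    """Brute-force AUC: concordant pairs + half ties over all pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.youden_j == pytest.approx(1.0)
        assert 3 < res.cutoff <= 10
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_six_point_toy_matches_pair_oracle(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        labels = np.array([0, 0, 1, 0, 1, 1])
        res = roc_youden(scores, labels)
        assert res.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scores=st.lists(st.integers(min_value=0, max_value=5), min_size=6, max_size=20),
        labels=st.lists(st.integers(min_value=0, max_value=1), min_size=6, max_size=20),
    )
    def test_auc_equals_pair_count_on_any_instance(self, scores, labels):
        n = min(len(scores), len(labels))
        scores = np.asarray(scores[:n], dtype=float)
        labels = np.asarray(labels[:n])
        if labels.sum() in (0, n):
            return  # one class absent: rejected elsewhere
        res = roc_youden(scores, labels)
        assert res.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    def test_youden_identity_and_tie_break(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 1, 0, 1])
        res = roc_youden(scores, labels)
        assert res.youden_j == pytest.approx(res.sensitivity + res.specificity - 1.0, abs=1e-12)
        # J is maximised (0.5) at cutoffs 2 and 4; tie broken to the lowest
        assert res.cutoff == 2.0

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        res = roc_youden(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_youden([1.0, 2.0], [1, 1])

    def test_reversed_orientation_noted(self):
        res = roc_youden([0, 1, 2, 3], [1, 1, 0, 0])
        assert res.auc < 0.5
        assert res.orientation_note is not None


class TestCohortReport:
    def test_default_cohort_report_structure(self):
        df = generate_cohort(seed=11)
        report = run_cohort_analysis(df)
        assert report["groups"] == {"healthy": 10, "HFpEF": 10, "HFrEF": 10}
        ecv = report["variables"]["ecv_pct"]
        assert ecv["anova"]["p"] < 0.05
        assert "ancova_age" in ecv
        # perfusion observed in two groups only (HFrEF excluded)
        assert sorted(report["variables"]["perf_stress"]["anova"]["groups_used"]) == ["HFpEF", "healthy"]
        assert set(report["roc"]) == {"HF_vs_healthy", "HFrEF_vs_HFpEF"}
        assert report["roc"]["HF_vs_healthy"]["auc"] > 0.7
        assert report["multiple_testing_correction"] == "none"
        assert report["n_tests_performed"] > 0

    def test_single_group_degenerates_to_descriptives(self):
        df = generate_cohort(seed=11)
        solo = df[df["group"] == "healthy"]
        report = run_cohort_analysis(solo)
        assert report["groups"] == {"healthy": 10}
        assert "anova" not in report["variables"]["ecv_pct"]
        assert report["roc"] == {}
        by_group = report["variables"]["ecv_pct"]["by_group"]["healthy"]
        assert by_group["n"] == 10
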