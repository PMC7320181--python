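"""Group classification, t-test, ICC(2,1) and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bodycomp.cohort_stats import (SubjectRecord, classify_group,
                                   classify_reliability, cohort_summary,
                                   icc_2_1, two_sample_ttest)
from bodycomp.errors import DataError, DegenerateDataError
from bodycomp.phantom import make_rater_pair
from bodycomp.quantify import CompartmentAreas, compute_ratios


class TestClassifyGroup:
    @pytest.mark.parametrize("bmi,alt,expected", [
        (29.4, 121.8, "sarcopenic-obesity"),   # group-mean anthropometrics
        (21.5, 34.7, "healthy"),
        (25.0, 35.0, "sarcopenic-obesity"),    # inclusive boundaries
        (18.0, 34.9, "healthy"),
        (23.0, 0.0, "healthy"),
        (24.0, 20.0, "unclassified"),          # between the bands
        (29.0, 20.0, "unclassified"),          # obese but normal ALT
        (21.0, 80.0, "unclassified"),          # normal BMI, high ALT
    ])
    def test_band_assignment(self, bmi, alt, expected):
        assert classify_group(bmi, alt) == expected

    def test_missing_value_error_names_field(self):
        with pytest.raises(DataError, match="BMI"):
            classify_group(float("nan"), 40.0)
        with pytest.raises(DataError, match="ALT"):
            classify_group(26.0, None)


class TestTwoSampleTTest:
    def test_closed_form_example(self):
        """A={1,2,3}, B={2,3,4}: pooled t = -1.2247 on 4 df, p ~ 0.288."""
        res = two_sample_ttest([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-np.sqrt(1.5), abs=1e-4)  # -1.22474
        assert res.df == 4
        expected_p = 2 * sps.t.cdf(-np.sqrt(1.5), 4)
        assert res.p == pytest.approx(expected_p, rel=1e-10)
        assert res.p == pytest.approx(0.288, abs=5e-4)

    def test_identical_means_give_t_zero_p_one(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.t == pytest.approx(0.0) and res.p == pytest.approx(1.0)

    def test_swapping_groups_negates_t_keeps_p(self):
        a, b = [1.0, 5.0, 2.0, 4.0], [2.0, 6.0, 7.0]
        r1, r2 = two_sample_ttest(a, b), two_sample_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_invariant_to_common_affine_transform(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.2, 15)
        r1 = two_sample_ttest(a, b)
        r2 = two_sample_ttest(3.2 * a - 7, 3.2 * b - 7)
        assert r1.t == pytest.approx(r2.t) and r1.p == pytest.approx(r2.p)
        assert r1.df == r2.df

    def test_degenerate_and_undersized_inputs_rejected(self):
        with pytest.raises(DegenerateDataError):
            two_sample_ttest([2.0, 2.0], [5.0, 5.0])
        with pytest.raises(DataError):
            two_sample_ttest([1.0], [2.0, 3.0])

    def test_welch_variant_reports_fractional_df(self):
        res = two_sample_ttest([1, 2, 3, 9], [2, 3, 4], welch=True)
        assert res.variant == "welch" and res.df != 5


class TestIcc:
    def test_identical_observers_give_icc_one(self):
        vals = np.array([3.0, 7.0, 1.0, 9.0, 4.0, 6.0])
        res = icc_2_1(np.column_stack([vals, vals]))
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_variance_components_recovered_at_large_n(self):
        """sigma_s^2=4, sigma_e^2=1 -> population ICC(2,1) = 0.8."""
        truth = np.random.default_rng(11).normal(0.0, 2.0, 5000)
        ratings = make_rater_pair(truth, (0.0, 0.0), error_sd=1.0, seed=5)
        res = icc_2_1(ratings)
        assert res.icc == pytest.approx(0.8, abs=0.02)

    def test_rater_offset_lowers_absolute_agreement(self):
        truth = np.random.default_rng(12).normal(0.0, 2.0, 50)
        base = icc_2_1(make_rater_pair(truth, (0.0, 0.0), 0.01, seed=1))
        offset = icc_2_1(make_rater_pair(truth, (0.0, 1.0), 0.01, seed=1))
        assert offset.icc < base.icc

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = make_rater_pair(rng.normal(50, 2, 20), (0.0, 1.5), 1.0, seed=3)
        res = icc_2_1(x)
        df = pd.DataFrame({"subj": np.repeat(np.arange(20), 2),
                           "rater": np.tile([0, 1], 20),
                           "score": x.ravel()})
        table = pg.intraclass_corr(df, targets="subj", raters="rater",
                                   ratings="score")
        ref = table[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert res.icc == pytest.approx(float(ref["ICC"]), rel=1e-10)
        assert res.p == pytest.approx(float(ref["pval"]), rel=1e-8)
        lo, hi = ref["CI95"]
        assert res.ci_lower == pytest.approx(float(lo), abs=5e-3)
        assert res.ci_upper == pytest.approx(float(hi), abs=5e-3)

    def test_ci_bounds_bracket_estimate(self):
        truth = np.random.default_rng(13).normal(0, 2, 30)
        res = icc_2_1(make_rater_pair(truth, (0, 0.5), 1.0, seed=2))
        assert res.ci_lower <= res.icc <= res.ci_upper <= 1.0

    def test_constant_ratings_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_2_1(np.full((6, 2), 5.0))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DataError):
            icc_2_1(np.arange(8.0).reshape(4, 2))

    def test_absolute_agreement_below_consistency_icc(self):
        """ICC(2,1) <= consistency-type ICC(3,1) on the same data."""
        truth = np.random.default_rng(14).normal(0, 2, 40)
        x = make_rater_pair(truth, (0.0, 1.2), 0.8, seed=4)
        res = icc_2_1(x)
        n, k = x.shape
        grand = x.mean()
        msr = k * np.var(x.mean(axis=1), ddof=1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        sse = ((x - grand) ** 2).sum() - msr * (n - 1) - msc * (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        icc3 = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc <= icc3 + 1e-12


class TestClassifyReliability:
    @pytest.mark.parametrize("icc,band", [
        (0.977, "excellent"),  # reported sarcopenic-obesity reliability
        (0.49, "poor"),
        (0.5, "moderate"),
        (0.75, "good"),
        (0.9, "good"),
        (0.901, "excellent"),
        (-0.2, "poor"),
    ])
    def test_bands(self, icc, band):
        assert classify_reliability(icc) == band

    def test_icc_above_one_rejected(self):
        with pytest.raises(DataError):
            classify_reliability(1.01)


def _record(sid, group, ma, sa, va):
    areas = CompartmentAreas(ma, sa, va)
    return SubjectRecord(subject_id=sid, bmi=25.0, alt=40.0, group=group,
                         areas=areas, ratios=compute_ratios(areas))


class TestCohortSummary:
    def test_equal_n_overall_mean_is_average_of_group_means(self):
        """Group MA means 14384.9 / 15492.2 -> overall 14938.55 (prints 14938.6);
        VA means 16224.6 / 12211.2 -> overall 14217.9."""
        recs = [_record("a1", "sarcopenic-obesity", 14384.9, 22337.2, 16224.6),
                _record("a2", "sarcopenic-obesity", 14384.9, 22337.2, 16224.6),
                _record("b1", "healthy", 15492.2, 10489.7, 12211.2),
                _record("b2", "healthy", 15492.2, 10489.7, 12211.2)]
        table = cohort_summary(recs)
        assert table.loc[("overall", "MA"), "mean"] == pytest.approx(14938.55)
        assert table.loc[("overall", "VA"), "mean"] == pytest.approx(14217.9)

    def test_overall_mean_is_pooled_mean_for_unequal_groups(self):
        recs = ([_record(f"a{i}", "g1", 100.0 + i, 50.0, 50.0) for i in range(3)]
                + [_record(f"b{i}", "g2", 200.0 + i, 60.0, 60.0) for i in range(5)])
        table = cohort_summary(recs)
        pooled = np.mean([100, 101, 102, 200, 201, 202, 203, 204])
        assert table.loc[("overall", "MA"), "mean"] == pytest.approx(pooled)

    def test_single_record_reports_sd_zero(self):
        table = cohort_summary([_record("x", "g", 100.0, 50.0, 25.0)])
        assert table.loc[("g", "MA"), "sd"] == 0.0
        assert table.loc[("g", "MA"), "mean"] == 100.0

    def test_group_sd_uses_n_minus_one(self):
        recs = [_record("a", "g", 10.0, 1.0, 1.0),
                _record("b", "g", 14.0, 1.0, 1.0)]
        table = cohort_summary(recs)
        assert table.loc[("g", "MA"), "sd"] == pytest.approx(np.sqrt(8.0))

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            cohort_summary([])
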