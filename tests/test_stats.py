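"""Cohort statistics: rank tests, chi-squared, mixed model, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from shgquant import (
    CohortConfig,
    CohortTable,
    PatientRecord,
    RandomInterceptModel,
    aggregate_patient,
    bmi_categorize,
    chi_squared,
    fit_random_intercept,
    generate_cohort,
    kruskal_wallis,
    mann_whitney_u,
    pooled_weighted_mean,
    summarize_cohort,
)
from shgquant.stats import render_report


class TestAggregatePatient:
    def test_simple_mean(self):
        df = pd.DataFrame(
            dict(patient_id=["p"] * 3, region_label="TSI", roi_index=[1, 2, 3],
                 metric="FB", value=[4.0, 6.0, 8.0])
        )
        out = aggregate_patient(df)
        assert out.value.iloc[0] == 6.0
        assert out.n_rois.iloc[0] == 3

    def test_single_roi_identity(self):
        df = pd.DataFrame(
            dict(patient_id=["p"], region_label=["TB"], roi_index=[1],
                 metric=["FAV"], value=[42.0])
        )
        assert aggregate_patient(df).value.iloc[0] == 42.0

    def test_matches_group_by_loop(self):
        cohort = generate_cohort(CohortConfig(n_patients_per_group=(8, 4), seed=5))
        out = aggregate_patient(cohort.measurements)
        expected = {}
        for row in cohort.measurements.itertuples():
            expected.setdefault((row.patient_id, row.region_label, row.metric), []).append(row.value)
        for row in out.itertuples():
            vals = expected[(row.patient_id, row.region_label, row.metric)]
            assert row.value == pytest.approx(np.mean(vals))
            assert row.n_rois == len(vals)

    def test_empty(self):
        assert aggregate_patient(pd.DataFrame(
            columns=["patient_id", "region_label", "roi_index", "metric", "value"]
        )).empty


def _mw_exact_enumeration(x, y):
    """Independent oracle: exact two-sided p by enumerating labelings."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    obs = u_of(range(n))
    mu = len(x) * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n)]
    return np.mean([abs(u - mu) >= abs(obs - mu) - 1e-12 for u in us])


class TestMannWhitney:
    def test_exact_small_sample(self):
        gc = mann_whitney_u([1, 2], [3, 4])
        assert gc.statistic == 0.0
        assert gc.p_value == pytest.approx(1 / 3)
        assert "exact" in gc.test_name

    def test_identical_multisets_u_is_half(self):
        x = [1.0, 2.0, 3.0]
        gc = mann_whitney_u(x, list(x))
        assert gc.statistic == pytest.approx(len(x) ** 2 / 2)

    def test_u_sum_identity(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=5)
        ux = mann_whitney_u(x, y).statistic
        uy = mann_whitney_u(y, x).statistic
        assert ux + uy == pytest.approx(35)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        gc = mann_whitney_u(x, y)
        assert "exact" in gc.test_name
        assert gc.p_value == pytest.approx(_mw_exact_enumeration(x, y), abs=1e-12)

    def test_ties_fall_back_to_asymptotic(self):
        gc = mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert "asymptotic" in gc.test_name

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquared:
    def test_printed_2x2_pt_table(self):
        # tumor-stage counts by group: reproduces the published p = 0.793
        gc = chi_squared([[53, 24], [8, 3]])
        assert gc.p_value == pytest.approx(0.793, abs=5e-4)
        assert "no continuity correction" in gc.test_name

    def test_proportional_rows_independent(self):
        gc = chi_squared([[10, 20], [1, 2]])
        assert gc.statistic == pytest.approx(0.0)
        assert gc.p_value == pytest.approx(1.0)

    def test_matches_expected_counts_formula(self):
        t = np.array([[53, 24], [8, 3]], float)
        total = t.sum()
        expected = np.outer(t.sum(1), t.sum(0)) / total
        stat = ((t - expected) ** 2 / expected).sum()
        assert chi_squared(t).statistic == pytest.approx(stat, rel=1e-12)

    def test_transposition_and_permutation_invariance(self, rng):
        t = rng.integers(1, 30, (3, 4))
        base = chi_squared(t).statistic
        assert chi_squared(t.T).statistic == pytest.approx(base)
        perm = t[[2, 0, 1]][:, [3, 1, 0, 2]]
        assert chi_squared(perm).statistic == pytest.approx(base)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-margin"):
            gc = chi_squared([[5, 3, 0], [2, 6, 0]])
        assert gc.p_value == pytest.approx(chi_squared([[5, 3], [2, 6]]).p_value)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [0, 0]])


class TestKruskalWallis:
    def test_maximal_separation(self):
        gc = kruskal_wallis([(1, 2, 3), (4, 5, 6), (7, 8, 9)])
        # fully separated ranks: mean ranks 2, 5, 8 -> H = 7.2, the
        # maximum for n=9, k=3 equal groups
        assert gc.statistic == pytest.approx(7.2)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(17)
        rejections = sum(
            kruskal_wallis([rng.normal(size=20) for _ in range(3)]).p_value < 0.05
            for _ in range(300)
        )
        assert 0.02 <= rejections / 300 <= 0.09

    def test_two_groups_agree_with_mann_whitney(self):
        rng = np.random.default_rng(23)
        agree = 0
        for _ in range(100):
            x = rng.integers(0, 12, size=25).astype(float)  # ties on purpose
            y = (rng.integers(0, 12, size=25) + rng.integers(0, 3, 25)).astype(float)
            kw = kruskal_wallis([x, y]).p_value < 0.05
            mw = mann_whitney_u(x, y).p_value < 0.05
            agree += kw == mw
        assert agree >= 95

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([(1.0, 2.0)])


class TestBMICategorize:
    @pytest.mark.parametrize(
        "bmi,expected",
        [(24.99, "normal"), (25.0, "overweight"), (29.99, "overweight"),
         (30.0, "obese"), (34.59, "obese"), (16.2, "normal")],
    )
    def test_boundaries(self, bmi, expected):
        assert bmi_categorize(bmi) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bmi_categorize(0.0)


class TestRandomIntercept:
    def _balanced(self, roi_noise=0.0, seed=0):
        # no between-patient heterogeneity: the random intercept is truly 0
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(6):
            for region, mu in (("TB", 10.0), ("TSI", 14.0)):
                for roi in (1, 2, 3):
                    rows.append(dict(patient_id=f"p{p}", region_label=region,
                                     roi_index=roi,
                                     value=mu + roi_noise * rng.standard_normal()))
        return pd.DataFrame(rows)

    def test_zero_patient_variance_collapses_to_mean_difference(self):
        # balanced design: the GLS fixed effect equals the plain
        # difference of region means whatever the variance split
        df = self._balanced(roi_noise=1.0)
        res = fit_random_intercept(df)
        diff = df[df.region_label == "TSI"].value.mean() - df[df.region_label == "TB"].value.mean()
        assert res.fixed_effects.loc["region_label[TSI]", "estimate"] == pytest.approx(diff, abs=1e-6)

    def test_effect_recovery_with_random_effects(self):
        means = {g: {"TSI": {"FB": 15.0, "FAV": 40.0}, "TB": {"FB": 10.0, "FAV": 44.0}}
                 for g in "AB"}
        cohort = generate_cohort(
            CohortConfig(n_patients_per_group=(200, 200), patient_sd=3.0,
                         roi_sd=2.0, group_means=means, seed=1)
        )
        fb = cohort.measurements[cohort.measurements.metric == "FB"]
        res = fit_random_intercept(fb, factor_col="region_label")
        est = res.fixed_effects.loc["region_label[TSI]", "estimate"]
        se = res.fixed_effects.loc["region_label[TSI]", "se"]
        assert abs(est - 5.0) < 3 * se

    def test_duplicating_rows_preserves_point_estimate(self):
        cohort = generate_cohort(CohortConfig(n_patients_per_group=(15, 10), seed=2))
        fb = cohort.measurements[cohort.measurements.metric == "FB"].copy()
        res1 = fit_random_intercept(fb)
        doubled = pd.concat(
            [fb, fb.assign(patient_id=fb.patient_id + "_dup")], ignore_index=True
        )
        res2 = fit_random_intercept(doubled)
        est1 = res1.fixed_effects["estimate"].to_numpy()
        est2 = res2.fixed_effects["estimate"].to_numpy()
        np.testing.assert_allclose(est1, est2, atol=1e-4)

    def test_results_object_summary(self):
        model = RandomInterceptModel.from_dataframe(self._balanced(roi_noise=1.0))
        res = model.fit()
        assert res.var_patient >= 0
        assert "Mixed" in str(res.summary())

    def test_too_few_patients_rejected(self):
        df = self._balanced(roi_noise=1.0)
        with pytest.raises(ValueError):
            RandomInterceptModel.from_dataframe(df[df.patient_id == "p0"])


class TestPooledWeightedMean:
    def test_published_fb_interface_mean(self):
        # per-group (mean, n) rows combine to the whole-cohort caption value
        assert pooled_weighted_mean([(16.08, 77), (18.69, 11)]) == pytest.approx(16.41, abs=0.01)

    def test_published_fav_bulk_mean(self):
        assert pooled_weighted_mean([(47.23, 223), (45.92, 20)]) == pytest.approx(47.12, abs=0.01)

    def test_equal_means_degenerate(self):
        assert pooled_weighted_mean([(5.0, 3), (5.0, 97)]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pooled_weighted_mean([])


class TestSummarizeCohort:
    def test_composition_percentages(self):
        cohort = generate_cohort(CohortConfig(n_patients_per_group=(77, 11), seed=0))
        report = summarize_cohort(cohort)
        assert report["composition"]["A"]["percent"] == pytest.approx(87.5)
        assert report["composition"]["B"]["percent"] == pytest.approx(12.5)
        assert "87.50%" in render_report(report)

    def test_single_patient_per_group_sd_missing(self):
        records = [
            PatientRecord(patient_id="a", group="A",
                          measurements=(("TSI", 1, "FB", 10.0),)),
            PatientRecord(patient_id="b", group="B",
                          measurements=(("TSI", 1, "FB", 12.0),)),
        ]
        report = summarize_cohort(CohortTable.from_records(records))
        entry = report["metrics"][0]
        assert np.isnan(entry["group_summaries"]["A"]["sd"])

    @pytest.mark.parametrize("seed", range(10))
    def test_categorical_percentages_sum_to_100(self, seed):
        cohort = generate_cohort(
            CohortConfig(n_patients_per_group=(20, 10), seed=seed)
        )
        report = summarize_cohort(cohort)
        for entry in report["covariates"]:
            if entry["type"] != "categorical":
                continue
            for g in report["groups"]:
                assert sum(entry["percents"][g]) == pytest.approx(100.0, abs=1e-9)

    def test_reports_both_rank_and_mixed_p(self):
        cohort = generate_cohort(CohortConfig(n_patients_per_group=(15, 10), seed=4))
        report = summarize_cohort(cohort)
        entry = report["metrics"][0]
        assert 0 <= entry["rank_test_p"] <= 1
        assert 0 <= entry["mixed_model_p"] <= 1
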