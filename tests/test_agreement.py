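"""Agreement statistics: correlations, ICC forms, binning, kappa, fixture."""

import numpy as np
import pandas as pd
import pytest

from hsiwound import (
    CaseRecord,
    bin_areas,
    cohen_kappa,
    compare_methods,
    exclude_outliers,
    icc_mixed,
    icc_single,
    pearson_r,
    reproduce_table4,
    spearman_rho,
    stage_summary,
)
from hsiwound.agreement import quantile_edges
from hsiwound.errors import ParameterError, StatisticsError

FLAGGED = ["Case 02", "Case 06", "Case 07", "Case 21", "Case 23",
           "Case 24", "Case 28"]


class TestFixture:
    def test_thirty_records_with_the_seven_flagged_outliers(self, study_records):
        assert len(study_records) == 30
        flagged = [r.case_id for r in study_records if r.outlier]
        assert flagged == FLAGGED

    def test_stage_distribution(self, study_records):
        summary = stage_summary(study_records).set_index("stage")
        assert summary.loc["2", "count"] == 13
        assert summary.loc["unstageable", "count"] == 4
        assert summary["count"].sum() == 30

    def test_outlier_exclusion_leaves_23(self, study_records):
        assert len(exclude_outliers(study_records)) == 23

    def test_exclusion_identity_and_total(self, study_records):
        assert exclude_outliers(study_records, []) == study_records
        everything = [r.case_id for r in study_records]
        assert exclude_outliers(study_records, everything) == []

    def test_unknown_id_rejected(self, study_records):
        with pytest.raises(ParameterError, match="Case 99"):
            exclude_outliers(study_records, ["Case 99"])

    def test_invalid_stage_rejected(self):
        with pytest.raises(ParameterError):
            CaseRecord("x", "5", 1.0, 1.0, 1.0)


class TestCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(1.0, 9.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticsError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base)
        assert spearman_rho(x, y**3) == pytest.approx(base)

    def test_spearman_equals_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 8, 20).astype(float)  # forces ties
        y = rng.integers(0, 8, 20).astype(float)

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
                i = j + 1
            return ranks

        expect = pearson_r(midranks(x), midranks(y))
        assert spearman_rho(x, y) == pytest.approx(expect)


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.arange(1.0, 9.0)
        assert icc_single(x, x, "oneway") == pytest.approx(1.0)
        assert icc_single(x, x, "twoway_agreement") == pytest.approx(1.0)

    def test_absolute_agreement_penalizes_offset(self, rng):
        x = rng.normal(10, 3, 15)
        y = x + 50.0
        assert icc_single(x, y, "twoway_agreement") < pearson_r(x, y) - 0.5

    def test_matches_explicit_anova_oracle(self, rng):
        x = rng.normal(size=6)
        y = x + rng.normal(0, 0.5, 6)
        data = np.column_stack([x, y])
        n, k = data.shape
        grand = data.mean()
        msb = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msw = ((data - data.mean(axis=1, keepdims=True)) ** 2).sum() / (
            n * (k - 1)
        )
        expect = (msb - msw) / (msb + (k - 1) * msw)
        assert icc_single(x, y, "oneway") == pytest.approx(expect)

    def test_matches_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(10, 3, 12)
        y = x + rng.normal(0, 1.5, 12) + 2.0
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile(["A", "B"], 12),
            "score": np.column_stack([x, y]).ravel(),
        })
        table = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        assert icc_single(x, y, "oneway") == pytest.approx(
            table.loc["ICC(1,1)", "ICC"]
        )
        assert icc_single(x, y, "twoway_agreement") == pytest.approx(
            table.loc["ICC(A,1)", "ICC"]
        )

    def test_mixed_zero_within_subject_variance_gives_one(self):
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(5), 3),
            "value": np.repeat([1.0, 2.0, 3.0, 4.0, 5.0], 3),
        })
        assert icc_mixed(df) == pytest.approx(1.0)

    def test_mixed_pure_noise_near_zero(self):
        estimates = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(20), 3),
                "value": r.normal(0, 1, 60),
            })
            estimates.append(icc_mixed(df))
        # truncating the negative between-subject component at zero gives
        # the null-case estimator a small positive bias
        assert np.mean(estimates) == pytest.approx(0.0, abs=0.1)

    def test_mixed_single_replicate_everywhere_rejected(self):
        df = pd.DataFrame({"subject": [0, 1, 2], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(StatisticsError):
            icc_mixed(df)


class TestBinning:
    def test_fixed_edges_direct_thresholding(self):
        cats = bin_areas(np.arange(1.0, 11.0), "fixed_edges", edges=[3.0, 7.0])
        np.testing.assert_array_equal(cats, [0, 0, 1, 1, 1, 1, 2, 2, 2, 2])

    def test_all_equal_values_one_category(self):
        cats = bin_areas(np.full(6, 4.2), "fixed_edges", edges=[1.0, 9.0])
        assert set(cats) == {1}

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ParameterError):
            bin_areas([1.0, 2.0], "fixed_edges", edges=[5.0, 3.0])
        with pytest.raises(ParameterError):
            bin_areas([1.0, 2.0], "fixed_edges", edges=[3.0, 3.0])

    def test_quintile_matches_sort_and_cut_oracle(self, rng):
        values = rng.uniform(0, 100, 30)
        cats = bin_areas(values, "quintile")
        edges = quantile_edges(values, 5)
        for v, c in zip(values, cats):
            assert c == int(np.sum(v >= edges))

    def test_quintile_needs_five_distinct(self):
        with pytest.raises(ParameterError):
            bin_areas([1.0, 1.0, 2.0, 2.0], "quintile")


class TestKappa:
    def test_identical_lists_give_one_for_all_weightings(self):
        a = np.array([0, 1, 2, 3, 4] * 4)
        for w in ("none", "linear", "quadratic"):
            assert cohen_kappa(a, a, w).kappa == pytest.approx(1.0)

    def test_two_by_two_hand_example(self):
        # counts: both-0 45, a0/b1 15, a1/b0 25, both-1 15 -> po=0.60, pe=0.54
        a = np.array([0] * 60 + [1] * 40)
        b = np.array([0] * 45 + [1] * 15 + [0] * 25 + [1] * 15)
        assert cohen_kappa(a, b).kappa == pytest.approx(0.06 / 0.46)

    def test_matches_sklearn_for_all_weightings(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        a = rng.integers(0, 5, 80)
        b = np.clip(a + rng.integers(-1, 2, 80), 0, 4)
        for mine, theirs in (("none", None), ("linear", "linear"),
                             ("quadratic", "quadratic")):
            assert cohen_kappa(a, b, mine).kappa == pytest.approx(
                sk.cohen_kappa_score(a, b, weights=theirs)
            )

    def test_linear_equals_unweighted_for_two_categories(self, rng):
        a = rng.integers(0, 2, 50)
        b = rng.integers(0, 2, 50)
        assert cohen_kappa(a, b, "linear").kappa == pytest.approx(
            cohen_kappa(a, b, "none").kappa
        )

    def test_ci_brackets_point_estimate(self, rng):
        a = rng.integers(0, 4, 60)
        b = np.clip(a + rng.integers(-1, 2, 60), 0, 3)
        res = cohen_kappa(a, b, "quadratic")
        assert -1.0 <= res.ci_low <= res.kappa <= res.ci_high <= 1.0

    def test_single_category_rejected(self):
        with pytest.raises(StatisticsError):
            cohen_kappa([1, 1, 1], [1, 1, 1])


class TestReports:
    def test_identical_columns_give_perfect_agreement(self):
        rng = np.random.default_rng(3)
        areas = rng.uniform(1, 50, 12)
        records = [
            CaseRecord(f"S{i:02d}", "2", a, a, a) for i, a in enumerate(areas)
        ]
        rep = compare_methods(records, "nurse_lw_cm2", "machine_lw_cm2")
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.icc_oneway == pytest.approx(1.0)
        assert rep.kappa_weighted.kappa == pytest.approx(1.0)

    def test_full_grid_has_six_reports_with_right_sizes(self, study_records):
        reports = reproduce_table4(study_records)
        assert len(reports) == 6
        for key, rep in reports.items():
            if key.endswith("__no_outliers"):
                assert rep.n == 23
                assert rep.excluded == FLAGGED
            else:
                assert rep.n == 30
            assert rep.binning == "pooled-quintile"

    def test_all_coefficients_in_unit_interval(self, study_records):
        for rep in reproduce_table4(study_records).values():
            for v in (rep.pearson_r, rep.spearman_rho, rep.icc_oneway,
                      rep.icc_agreement, rep.kappa_unweighted.kappa,
                      rep.kappa_weighted.kappa):
                assert -1.0 <= v <= 1.0
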