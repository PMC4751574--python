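"""Tests for reliability, covariate, screening and regression statistics."""

import numpy as np
import pandas as pd
import pytest

from cvikit import (apply_exclusions, bland_altman, coefficient_of_variation,
                    cohort_summary, derive_covariates, icc_absolute,
                    multivariate_fit, sample_cov, select_bp, univariate_screen)

from _oracles import anova_icc_oracle, ols_normal_equations


class TestCOV:
    def test_cohort_cvi_value(self):
        assert round(coefficient_of_variation(65.61, 2.33), 2) == 3.55

    def test_zero_dispersion(self):
        assert coefficient_of_variation(12.3, 0.0) == 0.0

    def test_sample_closed_form(self):
        assert sample_cov([1, 2, 3]) == pytest.approx(50.0)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation(0.0, 1.0)

    def test_scale_invariance(self, rng):
        x = rng.uniform(10, 20, 50)
        assert sample_cov(3.7 * x) == pytest.approx(sample_cov(x))


class TestICC:
    def test_identical_columns_give_one(self):
        y = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = icc_absolute(y)
        assert res.icc == 1.0
        assert res.ci_low == res.ci_high == 1.0

    def test_toy_table_matches_hand_anova(self):
        y = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 4.0], [6.0, 6.0]])
        msr, msc, mse, icc_expect = anova_icc_oracle(y)
        assert icc_absolute(y).icc == pytest.approx(icc_expect, abs=1e-12)

    def test_column_offset_penalized_despite_perfect_correlation(self, rng):
        x = rng.normal(size=(12,))
        shifted = np.column_stack([x, x + 50.0])
        _, _, _, icc_expect = anova_icc_oracle(shifted)
        res = icc_absolute(shifted)
        assert res.icc == pytest.approx(icc_expect, abs=1e-12)
        assert res.icc < 0.1  # absolute agreement, not consistency

    def test_grand_shift_invariance(self, rng):
        y = rng.normal(10, 2, size=(8, 3))
        assert icc_absolute(y + 123.4).icc == pytest.approx(icc_absolute(y).icc)

    def test_single_column_offset_strictly_decreases_icc(self, rng):
        y = np.column_stack([rng.normal(size=10), rng.normal(size=10)])
        y[:, 1] = y[:, 0] + rng.normal(0, 0.05, 10)
        base = icc_absolute(y).icc
        shifted = y.copy()
        shifted[:, 1] += 2.0
        assert icc_absolute(shifted).icc < base

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        y = rng.normal(50, 5, size=(15, 2)) + rng.normal(0, 1, size=(15, 1))
        df = pd.DataFrame(y, columns=["r1", "r2"]).reset_index().melt(
            id_vars="index", var_name="rater", value_name="score")
        ref = pingouin.intraclass_corr(data=df, targets="index", raters="rater",
                                       ratings="score").set_index("Type")
        mine = icc_absolute(y)
        assert mine.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        lo, hi = ref.loc["ICC(A,1)", "CI95"]  # pingouin rounds the CI to 2 dp
        assert mine.ci_low == pytest.approx(lo, abs=0.011)
        assert mine.ci_high == pytest.approx(hi, abs=0.011)

    def test_constant_table_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            icc_absolute(np.full((5, 2), 3.0))


class TestBlandAltman:
    def test_identical_vectors(self):
        r = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert (r.mean_diff, r.sd_diff, r.loa_low, r.loa_high) == (0, 0, 0, 0)

    def test_constant_offset_collapses_loa(self, rng):
        x = rng.normal(size=20)
        r = bland_altman(x, x - 0.7)
        assert r.mean_diff == pytest.approx(0.7)
        assert r.sd_diff == pytest.approx(0.0, abs=1e-12)
        assert r.loa_low == pytest.approx(r.loa_high)

    def test_random_pairs_match_direct_formula(self, rng):
        x, y = rng.normal(size=35), rng.normal(size=35)
        r = bland_altman(x, y)
        d = x - y
        assert r.mean_diff == pytest.approx(d.mean())
        assert r.sd_diff == pytest.approx(d.std(ddof=1))
        assert r.loa_high - r.mean_diff == pytest.approx(1.96 * r.sd_diff)

    def test_antisymmetry_under_argument_swap(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        a, b = bland_altman(x, y), bland_altman(y, x)
        assert b.mean_diff == pytest.approx(-a.mean_diff)
        assert b.loa_low == pytest.approx(-a.loa_high)
        assert b.loa_high == pytest.approx(-a.loa_low)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman([1.0], [2.0])


class TestDerivedCovariates:
    def test_formulas(self):
        df = pd.DataFrame({"sbp_mmhg": [90.0, 120.0], "dbp_mmhg": [90.0, 80.0],
                           "iop_mmhg": [15.0, 15.0],
                           "sphere_d": [-2.0, 0.0], "cylinder_d": [-1.0, 0.0],
                           "weight_kg": [81.0, 60.0], "height_m": [1.8, 1.5]})
        out = derive_covariates(df)
        assert out.loc[0, "map_mmhg"] == pytest.approx(90.0)
        assert out.loc[0, "opp_mmhg"] == pytest.approx(45.0)
        assert out.loc[0, "se_d"] == pytest.approx(-2.5)
        assert out.loc[0, "bmi"] == pytest.approx(25.0)
        assert out.loc[1, "map_mmhg"] == pytest.approx(80 + 40 / 3)

    def test_nonpositive_height_rejected(self):
        df = pd.DataFrame({"weight_kg": [70.0], "height_m": [0.0]})
        with pytest.raises(ValueError, match="height"):
            derive_covariates(df)


class TestSelectBP:
    def test_two_readings_mean(self):
        assert select_bp([(120, 80), (122, 82)]) == (121, 81)

    def test_third_reading_picks_closest_systolic_pair(self):
        assert select_bp([(120, 80), (140, 90), (138, 88)]) == (139, 89)

    def test_exact_duplicate_pair_wins(self):
        assert select_bp([(120, 80), (120, 80), (200, 110)]) == (120, 80)

    def test_systolic_tie_broken_by_diastolic(self):
        # pairs (0,1) and (0,2) both have systolic gap 10; diastolic gaps 8 vs 2.
        assert select_bp([(120, 80), (130, 88), (110, 78)]) == (115, 79)

    def test_single_reading_rejected(self):
        with pytest.raises(ValueError):
            select_bp([(120, 80)])


class TestExclusions:
    def test_fixture_cohort_retains_345(self, screening_cohort):
        retained, tally = apply_exclusions(screening_cohort)
        assert len(retained) == 345
        assert tally == {"visual_acuity": 9, "spherical_equivalent": 7,
                         "glaucoma": 6, "retinal_disease": 18, "scan_quality": 15}
        assert sum(tally.values()) == 400 - 345

    def test_empty_cohort(self):
        retained, tally = apply_exclusions(pd.DataFrame())
        assert len(retained) == 0
        assert sum(tally.values()) == 0

    def test_double_failure_counted_under_first_criterion(self, screening_cohort):
        df = screening_cohort.copy()
        df.loc[399, "logmar_va"] = 0.9  # also fails quality -> attributed to VA
        _, tally = apply_exclusions(df)
        assert tally["visual_acuity"] == 10
        assert tally["scan_quality"] == 14

    def test_missing_field_names_record(self, screening_cohort):
        df = screening_cohort.copy()
        df.loc[3, "scan_quality_db"] = np.nan
        with pytest.raises(ValueError, match="P003.*scan_quality_db"):
            apply_exclusions(df)

    def test_summary_reports_female_percent(self, screening_cohort):
        retained, _ = apply_exclusions(screening_cohort)
        summary = cohort_summary(retained)
        assert round(summary["percent_female"]) == 55


def _printed_univariate_pvalues(table: str) -> tuple[dict, set]:
    """Univariate p-values printed for each candidate, and the set the
    p < 0.10 rule should select (the multivariable column membership)."""
    if table == "sfct":
        pvals = {"axial_length": 0.005, "iop": 0.087, "opp": 0.572, "la": 1e-4,
                 "sa": 1e-4, "age": 1e-4, "gender": 0.034, "bmi": 0.252,
                 "sbp": 0.050, "dbp": 0.122, "glucose": 0.949, "hba1c": 0.157,
                 "cholesterol": 0.052, "triglycerides": 0.366,
                 "creatinine": 0.754, "smoking": 0.031, "alcohol": 0.651}
        expected = {"axial_length", "iop", "la", "sa", "age", "gender", "sbp",
                    "cholesterol", "smoking"}
    else:
        pvals = {"axial_length": 0.039, "iop": 0.745, "opp": 0.136,
                 "sfct": 1e-4, "age": 1e-4, "gender": 0.005, "bmi": 0.283,
                 "sbp": 0.818, "dbp": 0.007, "glucose": 0.511, "hba1c": 0.736,
                 "cholesterol": 0.256, "triglycerides": 0.158,
                 "creatinine": 0.516, "smoking": 1e-4, "alcohol": 0.341}
        expected = {"axial_length", "sfct", "age", "gender", "dbp", "smoking"}
    return pvals, expected


class TestRegressionWorkflow:
    @pytest.mark.parametrize("table,n_selected", [("sfct", 9), ("cvi", 6)])
    def test_screen_rule_reproduces_published_variable_sets(self, table, n_selected):
        pvals, expected = _printed_univariate_pvalues(table)
        selected = {v for v, p in pvals.items() if p < 0.10}
        assert selected == expected
        assert len(selected) == n_selected

    def test_noiseless_linear_relation_selected(self):
        x = np.arange(30.0)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        selected, rows = univariate_screen(df, "y", ["x"])
        assert selected == ["x"]
        assert rows[0].beta_unstd == pytest.approx(2.0)
        assert rows[0].beta_std == pytest.approx(1.0)
        assert rows[0].p_value < 1e-10

    def test_zero_variance_predictor_excluded_with_warning(self, rng):
        df = pd.DataFrame({"x": np.ones(20), "y": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="zero variance"):
            selected, rows = univariate_screen(df, "y", ["x"])
        assert selected == [] and rows == []

    def test_orthogonal_design_equals_univariate_slopes(self):
        n = 40
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 3 * x1 - 2 * x2 + 0.5
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        _, uni = univariate_screen(df, "y", ["x1", "x2"], alpha=1.1)
        multi = multivariate_fit(df, "y", ["x1", "x2"])
        for u, m in zip(uni, multi):
            assert m.beta_unstd == pytest.approx(u.beta_unstd, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(50, 3))
        beta = np.array([1.5, -2.0, 0.3])
        y = 4.0 + X @ beta + rng.normal(0, 0.1, 50)
        df = pd.DataFrame(X, columns=["a", "b", "c"]).assign(y=y)
        rows = multivariate_fit(df, "y", ["a", "b", "c"])
        expect = ols_normal_equations(X, y)
        for i, row in enumerate(rows):
            assert row.beta_unstd == pytest.approx(expect[i + 1], abs=1e-10)

    def test_rank_deficient_design_names_collinear_columns(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=30)})
        with pytest.raises(ValueError, match="collinear.*x"):
            multivariate_fit(df, "y", ["x", "x2"])

    def test_screen_then_fit_deterministic(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0] - 0.5 * X[:, 2] + rng.normal(0, 0.5, 60)
        df = pd.DataFrame(X, columns=list("abcd")).assign(y=y)
        run1 = univariate_screen(df, "y", list("abcd"))
        run2 = univariate_screen(df, "y", list("abcd"))
        assert run1 == run2
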