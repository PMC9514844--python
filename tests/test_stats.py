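"""Partial correlations, bootstrap CIs, dependent-correlation test, ICC, battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tractvelocity.stats import (
    SingularDesignError,
    UndefinedCorrelationError,
    bonferroni_threshold,
    bootstrap_ci,
    compare_dependent_correlations,
    icc_absolute_agreement,
    partial_correlation,
    partial_correlation_with_ci,
    precheck_voxelcount,
    run_association_battery,
)


def precision_matrix_partial_r(x, y, covariates):
    """Independent oracle: partial r from the inverse correlation matrix."""
    M = np.column_stack([x, y, covariates])
    R = np.corrcoef(M, rowvar=False)
    P = np.linalg.inv(R)
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=(2, 40))
        res = partial_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)
        assert res.k == 0 and res.df == 38

    def test_identical_variables_give_unit_correlation(self, rng):
        x = rng.normal(size=30)
        C = rng.normal(size=(30, 2))
        res = partial_correlation(x, x, C)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_small_worked_example_against_precision_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        z = np.array([1.0, 1, 2, 2, 3])
        res = partial_correlation(x, y, z)
        assert res.r == pytest.approx(precision_matrix_partial_r(x, y, z[:, None]), abs=1e-12)
        assert res.df == 5 - 2 - 1

    def test_singular_design_rejected(self, rng):
        x, y = rng.normal(size=(2, 20))
        c = rng.normal(size=20)
        with pytest.raises(SingularDesignError):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))

    def test_zero_residual_variance_rejected(self, rng):
        c = np.asarray(np.r_[np.zeros(10), np.ones(10)])
        y = np.asarray(np.random.default_rng(0).normal(size=20))
        with pytest.raises(UndefinedCorrelationError):
            partial_correlation(c, y, c)  # x fully explained by the covariate


class TestBootstrapCI:
    def test_degenerate_perfect_correlation(self, rng):
        x = rng.normal(size=25)
        lo, hi = bootstrap_ci(x, x, n_boot=300, seed=0)
        assert lo == pytest.approx(1.0, abs=1e-9)
        assert hi == pytest.approx(1.0, abs=1e-9)

    def test_identical_seed_identical_interval(self, rng):
        x, y = rng.normal(size=(2, 50))
        C = rng.normal(size=(50, 3))
        a = bootstrap_ci(x, y, C, n_boot=500, seed=42)
        b = bootstrap_ci(x, y, C, n_boot=500, seed=42)
        assert a == b
        c = bootstrap_ci(x, y, C, n_boot=500, seed=43)
        assert a != c

    def test_interval_brackets_point_estimate(self, rng):
        x, y = rng.normal(size=(2, 80))
        y = y + 0.5 * x
        res = partial_correlation_with_ci(x, y, n_boot=1000, seed=1)
        assert res.ci_low < res.r < res.ci_high

    def test_bad_level_rejected(self, rng):
        x, y = rng.normal(size=(2, 30))
        with pytest.raises(ValueError):
            bootstrap_ci(x, y, n_boot=200, level=1.2, seed=0)

    def test_bca_runs_and_is_sane(self, rng):
        x, y = rng.normal(size=(2, 60))
        y = y + 0.4 * x
        lo, hi = bootstrap_ci(x, y, n_boot=600, seed=2, method="bca")
        assert -1 <= lo < hi <= 1


class TestDependentCorrelationComparison:
    def test_equal_correlations_give_zero(self):
        c = compare_dependent_correlations(0.4, 0.4, 0.2, 100)
        assert c.z == 0.0
        assert c.p == pytest.approx(1.0)
        assert c.r_difference == 0.0

    def test_published_formula_example(self):
        # independent step-by-step evaluation: z1-z2 = .23975,
        # rbar2 = .17, f = .36145, h = 1.13078, z = 2.0585
        c = compare_dependent_correlations(0.5, 0.3, 0.4, 103)
        assert c.z == pytest.approx(2.0585, abs=1e-3)
        assert round(c.z, 2) == 2.06

    def test_z_monotone_in_n(self):
        zs = [abs(compare_dependent_correlations(0.5, 0.3, 0.4, n).z) for n in (10, 50, 200)]
        assert zs == sorted(zs)

    def test_antisymmetric_under_swap(self):
        a = compare_dependent_correlations(0.5, 0.2, 0.3, 80)
        b = compare_dependent_correlations(0.2, 0.5, 0.3, 80)
        assert a.z == pytest.approx(-b.z)
        assert np.sign(a.z) == np.sign(a.r1 - a.r2)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_out_of_range_correlations_rejected(self, bad):
        with pytest.raises(ValueError):
            compare_dependent_correlations(bad, 0.2, 0.1, 50)


class TestBonferroni:
    def test_study_threshold(self):
        thr = bonferroni_threshold(0.05, 3)
        assert thr == pytest.approx(0.016667, abs=1e-6)
        assert round(thr, 3) == 0.017

    def test_identity_and_monotonicity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 5) < bonferroni_threshold(0.05, 4)


class TestICC:
    # frozen oracle: two-way ANOVA mean squares on this 6x2 matrix,
    # cross-checked against an independent implementation
    RATINGS = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 7], [10, 9]], float)

    def test_fixed_matrix_against_anova_oracle(self):
        res = icc_absolute_agreement(self.RATINGS)
        assert res.icc_single == pytest.approx(-0.353591, abs=1e-6)
        assert res.icc_average == pytest.approx(-1.094017, abs=1e-6)

    def test_cross_check_with_pingouin(self):
        pg = pytest.importorskip("pingouin")
        n, k = self.RATINGS.shape
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": self.RATINGS.ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref = table.set_index("Type")["ICC"]
        res = icc_absolute_agreement(self.RATINGS)
        assert res.icc_single == pytest.approx(ref["ICC(A,1)"], abs=1e-9)
        assert res.icc_average == pytest.approx(ref["ICC(A,k)"], abs=1e-9)

    def test_duplicated_raters_give_perfect_agreement(self):
        col = np.array([3.0, 1, 4, 1, 5, 9])
        res = icc_absolute_agreement(np.column_stack([col, col]))
        assert res.icc_single == pytest.approx(1.0)
        assert res.icc_average == pytest.approx(1.0)

    def test_rater_offset_lowers_absolute_agreement(self, rng):
        base = rng.normal(10, 3, size=12)
        noisy = base + rng.normal(0, 0.5, size=12)
        no_offset = icc_absolute_agreement(np.column_stack([base, noisy]))
        offset = icc_absolute_agreement(np.column_stack([base, noisy + 3.0]))
        assert offset.icc_single < no_offset.icc_single

    def test_average_at_least_single_when_nonnegative(self, rng):
        base = rng.normal(size=15)
        R = np.column_stack([base + rng.normal(0, 0.4, 15) for _ in range(3)])
        res = icc_absolute_agreement(R)
        if res.icc_single >= 0:
            assert res.icc_average >= res.icc_single

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            icc_absolute_agreement(np.full((5, 2), 3.0))


def make_cohort(rng, n=120, tracts=("t1",), effect=0.0):
    """Minimal synthetic cohort frame for battery tests."""
    df = pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "age": rng.normal(30, 5, n),
            "gender": rng.integers(0, 2, n),
            "scanner": rng.integers(1, 4, n),
            "internal_details": rng.normal(24, 7, n),
            "external_details": rng.normal(5, 3, n),
        }
    )
    for t in tracts:
        df[f"{t}__n_voxels"] = rng.normal(129, 26, n).round()
        df[f"{t}__g_ratio"] = rng.normal(0.65, 0.04, n) + effect * (
            df["internal_details"] - 24
        ) / 7 * 0.04
        df[f"{t}__mtsat"] = rng.normal(0.96, 0.007, n)
    return df


class TestPrecheck:
    def test_df_rule_with_three_covariates(self, rng):
        df = make_cohort(rng, n=60)
        out = precheck_voxelcount(df, ["t1"])
        assert out["t1"].df == 60 - 5  # k = 3, voxel count is the tested variable

    def test_constant_voxel_count_surfaces_error(self, rng):
        df = make_cohort(rng, n=40)
        df["t1__n_voxels"] = 100
        out = precheck_voxelcount(df, ["t1"])
        assert isinstance(out["t1"], UndefinedCorrelationError)


class TestBattery:
    def test_empty_metrics_give_empty_report(self, rng):
        report = run_association_battery(make_cohort(rng), ["t1"], [], n_boot=0)
        assert report.results.empty
        assert report.comparisons.empty

    def test_row_layout_and_threshold_tiers(self, rng):
        df = make_cohort(rng, n=100, tracts=("t1", "t2", "t3", "t4"))
        report = run_association_battery(
            df, ["t1", "t2", "t3", "t4"], ["g_ratio"], n_boot=0, m_tracts=3
        )
        assert len(report.results) == 4 * 1 * 2  # tract x metric x two outcomes
        tiers = report.results.groupby("tract")["tier"].first()
        assert (tiers[["t1", "t2", "t3"]] == "primary").all()
        assert tiers["t4"] == "exploratory"
        primary_thr = report.results.query("tier == 'primary'")["threshold"].unique()
        assert primary_thr == pytest.approx([0.05 / 3])

    def test_comparison_gated_on_primary_significance(self, rng):
        strong = make_cohort(rng, n=200, effect=3.0)  # strong g-ratio association
        report = run_association_battery(strong, ["t1"], ["g_ratio", "mtsat"], n_boot=0)
        res = report.results.set_index(["metric", "outcome"])
        assert res.loc[("g_ratio", "internal_details"), "significant"]
        compared = set(report.comparisons["metric"])
        sig = {
            m
            for m in ("g_ratio", "mtsat")
            if res.loc[(m, "internal_details"), "significant"]
        }
        assert compared == sig  # comparison runs exactly for significant cells

    def test_null_cohort_rarely_triggers_comparisons(self, rng):
        report = run_association_battery(
            make_cohort(rng, n=150), ["t1"], ["g_ratio"], n_boot=0
        )
        nonsig = report.results.query("~significant")
        for _, row in nonsig.iterrows():
            assert not (
                (report.comparisons["tract"] == row["tract"])
                & (report.comparisons["metric"] == row["metric"])
            ).any()

    def test_scenario_attached_from_g_and_mtsat(self, rng):
        df = make_cohort(rng, n=200, effect=3.0)
        report = run_association_battery(df, ["t1"], ["g_ratio", "mtsat"], n_boot=0)
        assert "t1" in report.scenarios
        assert report.scenarios["t1"].scenario.value == "axon_diameter_dominant"

    def test_duplicate_participants_rejected(self, rng):
        df = make_cohort(rng, n=20)
        df.loc[1, "participant_id"] = df.loc[0, "participant_id"]
        with pytest.raises(ValueError, match="duplicated"):
            run_association_battery(df, ["t1"], ["g_ratio"], n_boot=0)

    def test_constant_covariate_dropped_not_fatal(self, rng):
        df = make_cohort(rng, n=80)
        df["scanner"] = 1  # single-scanner cohort
        report = run_association_battery(df, ["t1"], ["g_ratio"], n_boot=0)
        assert len(report.results) == 2
        # one fewer covariate in the design
        assert (report.results["df"] == 80 - 2 - 3).all()

    def test_battery_determinism_with_seed(self, rng):
        df = make_cohort(rng, n=80)
        a = run_association_battery(df, ["t1"], ["g_ratio"], n_boot=200, seed=9)
        b = run_association_battery(df, ["t1"], ["g_ratio"], n_boot=200, seed=9)
        pd.testing.assert_frame_equal(a.results, b.results)
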