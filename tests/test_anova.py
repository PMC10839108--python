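import numpy as np
import pytest
from scipy import stats

from cortivar.anova import (
    AnovaDecomposition,
    AnovaTerm,
    DegenerateDataError,
    cohens_d_combined,
    fit_two_way_anova,
    mean_sd_regression,
    residual_diagnostics,
    tukey_batch_comparisons,
)
from cortivar.cohort import BatchSummary, Cohort, batch_summaries
from cortivar.reference import (
    FIELD_STUDY_COHENS_D,
    FIELD_STUDY_TABLE,
    field_study_summaries,
)
from cortivar.simulate import SimulationParams, generate_cohort

from conftest import make_cohort


def brute_force_sequential_ss(farms, batches, y):
    """Independent sequential-SS oracle built on explicit projections."""
    y = np.asarray(y, dtype=float)

    def proj_rss(columns):
        X = np.column_stack(columns)
        P = X @ np.linalg.pinv(X)
        r = y - P @ y
        return float(r @ r)

    ones = np.ones(len(y))
    b_dummies = [np.asarray(batches) == lv for lv in sorted(set(batches))]
    f_dummies = [np.asarray(farms) == lv for lv in sorted(set(farms))]
    cells = [f"{f}|{b}" for f, b in zip(farms, batches)]
    c_dummies = [np.asarray(cells) == lv for lv in sorted(set(cells))]

    rss0 = proj_rss([ones])
    rss_b = proj_rss([ones, *b_dummies])
    rss_bf = proj_rss([ones, *b_dummies, *f_dummies])
    rss_full = proj_rss([ones, *c_dummies])
    return {
        "batch": rss0 - rss_b,
        "farm": rss_b - rss_bf,
        "batch:farm": rss_bf - rss_full,
        "residuals": rss_full,
    }


TOY_8 = {
    ("F1", "1"): [3.0, 5.0],
    ("F1", "2"): [9.0, 11.0],
    ("F2", "1"): [4.0, 4.5],
    ("F2", "2"): [6.0, 13.0],
}


class TestFitTwoWayAnova:
    def test_all_equal_is_degenerate(self):
        cohort = make_cohort({("A", "1"): [5.0, 5.0], ("B", "1"): [5.0, 5.0],
                              ("A", "2"): [5.0, 5.0], ("B", "2"): [5.0, 5.0]})
        with pytest.raises(DegenerateDataError, match="zero total variance"):
            fit_two_way_anova(cohort)

    def test_missing_cell_is_explicit_error(self):
        cohort = make_cohort({("A", "1"): [1.0, 2.0], ("A", "2"): [3.0, 4.0],
                              ("B", "1"): [5.0, 6.0]})
        with pytest.raises(DegenerateDataError, match="farm 'B'"):
            fit_two_way_anova(cohort)

    def test_toy_matches_projection_oracle(self):
        cohort = make_cohort(TOY_8)
        decomp = fit_two_way_anova(cohort)
        farms = [r.farm_id for r in cohort.records]
        batches = [r.batch_id for r in cohort.records]
        expected = brute_force_sequential_ss(farms, batches, cohort.hcc)
        for name, ss in expected.items():
            assert decomp.term(name).sum_of_squares == pytest.approx(ss, abs=1e-9)

    def test_matches_statsmodels_type1(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        cohort, _ = generate_cohort(
            SimulationParams(n_farms=5, grand_mean=100.0, seed=8,
                             noise_family="additive_gaussian",
                             dropout=((0, 1, 3), (2, 0, 1)))
        )
        decomp = fit_two_way_anova(cohort)
        model = smf.ols(
            "hcc_pg_mg ~ C(batch_id) + C(farm_id) + C(batch_id):C(farm_id)",
            cohort.to_frame(),
        ).fit()
        table = anova_lm(model, typ=1)
        expected = dict(
            zip(("batch", "farm", "batch:farm", "residuals"), table["sum_sq"])
        )
        expected_p = dict(
            zip(("batch", "farm", "batch:farm"), table["PR(>F)"])
        )
        for name in ("batch", "farm", "batch:farm", "residuals"):
            assert decomp.term(name).sum_of_squares == pytest.approx(expected[name])
        for name in ("batch", "farm", "batch:farm"):
            assert decomp.term(name).p == pytest.approx(expected_p[name])

    def test_eta_squared_sums_to_one_and_ss_additivity(self):
        for seed in range(5):
            cohort, _ = generate_cohort(
                SimulationParams(n_farms=4, n_pigs_per_batch=6, grand_mean=50.0,
                                 seed=seed, noise_family="lognormal")
            )
            decomp = fit_two_way_anova(cohort)
            etas = [t.eta_squared for t in decomp.terms]
            assert sum(etas) == pytest.approx(1.0)
            assert all(0.0 <= e <= 1.0 for e in etas)
            assert sum(t.sum_of_squares for t in decomp.terms) == pytest.approx(
                decomp.ss_total
            )
            assert sum(t.df for t in decomp.terms) == len(cohort) - 1

    def test_invariant_to_within_cell_relabeling(self):
        cohort = make_cohort(TOY_8)
        swapped = make_cohort({k: list(reversed(v)) for k, v in TOY_8.items()})
        d1, d2 = fit_two_way_anova(cohort), fit_two_way_anova(swapped)
        for t1, t2 in zip(d1.terms, d2.terms):
            assert t1.sum_of_squares == pytest.approx(t2.sum_of_squares)

    def test_balanced_design_sequential_equals_marginal(self):
        # on a balanced design Type I == Type II
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        cohort, _ = generate_cohort(
            SimulationParams(n_farms=4, n_pigs_per_batch=5, grand_mean=100.0,
                             seed=2, noise_family="additive_gaussian")
        )
        decomp = fit_two_way_anova(cohort)
        model = smf.ols(
            "hcc_pg_mg ~ C(batch_id) + C(farm_id) + C(batch_id):C(farm_id)",
            cohort.to_frame(),
        ).fit()
        t2 = anova_lm(model, typ=2)
        assert decomp.term("batch").sum_of_squares == pytest.approx(
            t2.loc["C(batch_id)", "sum_sq"]
        )
        assert decomp.term("farm").sum_of_squares == pytest.approx(
            t2.loc["C(farm_id)", "sum_sq"]
        )


def _decomposition_from_residuals(resid, cell_index=None):
    resid = np.asarray(resid, dtype=float)
    if cell_index is None:
        cell_index = np.zeros(len(resid), dtype=int)
        cell_index[len(resid) // 2:] = 1
    term = AnovaTerm("residuals", float(resid @ resid), len(resid) - 1,
                     float(resid @ resid) / max(len(resid) - 1, 1), None, None, 1.0)
    return AnovaDecomposition(
        terms=[term], ss_total=float(resid @ resid) or 1.0, n_obs=len(resid),
        residuals=resid, cell_index=np.asarray(cell_index),
    )


class TestResidualDiagnostics:
    def test_gaussian_residuals_pass_shapiro_mostly(self):
        rng = np.random.default_rng(0)
        hits = sum(
            residual_diagnostics(
                _decomposition_from_residuals(rng.normal(size=500))
            )["shapiro"]["p"] > 0.05
            for _ in range(100)
        )
        assert hits >= 90

    def test_exponential_residuals_fail_shapiro(self):
        rng = np.random.default_rng(1)
        hits = sum(
            residual_diagnostics(
                _decomposition_from_residuals(rng.exponential(size=500) - 1.0)
            )["shapiro"]["p"] < 0.05
            for _ in range(100)
        )
        assert hits >= 99

    @pytest.mark.filterwarnings("ignore:scipy.stats.shapiro")
    def test_no_dispersion_gives_zero_levene(self):
        report = residual_diagnostics(_decomposition_from_residuals([0.0] * 6))
        assert report["levene"]["statistic"] == 0.0

    def test_tiny_sample_flags_normality_unavailable(self):
        report = residual_diagnostics(_decomposition_from_residuals([0.5, -0.5]))
        assert report["shapiro"] is None
        assert any("n < 3" in f for f in report["flags"])

    def test_levene_center_configurable(self):
        rng = np.random.default_rng(2)
        decomp = _decomposition_from_residuals(rng.normal(size=40))
        r1 = residual_diagnostics(decomp, levene_center="median")
        r2 = residual_diagnostics(decomp, levene_center="mean")
        assert r1["levene"]["center"] == "median"
        assert r2["levene"]["statistic"] != r1["levene"]["statistic"]
        with pytest.raises(ValueError):
            residual_diagnostics(decomp, levene_center="mode")

    def test_qq_coordinates_sorted(self):
        rng = np.random.default_rng(3)
        report = residual_diagnostics(_decomposition_from_residuals(rng.normal(size=50)))
        assert report["qq"]["sample"] == sorted(report["qq"]["sample"])


class TestTukeyBatchComparisons:
    def test_equal_batch_means_give_p_near_one(self):
        cohort = make_cohort({("A", "1"): [9.0, 11.0], ("A", "2"): [8.0, 12.0],
                              ("B", "1"): [19.0, 21.0], ("B", "2"): [18.0, 22.0]})
        comps = tukey_batch_comparisons(cohort)
        assert all(c.adjusted_p > 0.99 for c in comps)
        assert not any(c.significant for c in comps)

    def test_within_farm_family_matches_t_test_identity(self):
        # with k=2 the studentized range reduces to q = t * sqrt(2)
        cohort = make_cohort(TOY_8)
        decomp = fit_two_way_anova(cohort)
        mse = decomp.term("residuals").mean_square
        df = decomp.term("residuals").df
        for comp in tukey_batch_comparisons(cohort, family="within_farm"):
            n1 = n2 = 2
            t = abs(comp.mean_diff) / np.sqrt(mse * (1 / n1 + 1 / n2))
            expected = 2 * stats.t.sf(t, df)
            assert comp.adjusted_p == pytest.approx(expected, rel=1e-6)

    def test_all_cells_family_is_more_conservative(self):
        cohort = make_cohort(TOY_8)
        full = tukey_batch_comparisons(cohort, family="all_cells")
        narrow = tukey_batch_comparisons(cohort, family="within_farm")
        for f, n in zip(full, narrow):
            assert f.adjusted_p >= n.adjusted_p

    def test_reference_reconstruction_reproduces_significance(self):
        from cortivar.reference import FIELD_STUDY_SIGNIFICANT, field_study_cohort

        comps = {c.farm_id: c for c in tukey_batch_comparisons(field_study_cohort(0))}
        for farm in FIELD_STUDY_SIGNIFICANT["p<0.001"]:
            assert comps[farm].adjusted_p < 0.001
        for farm in FIELD_STUDY_SIGNIFICANT["p<0.05"]:
            assert comps[farm].adjusted_p < 0.05
        for farm, comp in comps.items():
            printed_significant = any(
                farm in farms for farms in FIELD_STUDY_SIGNIFICANT.values()
            )
            assert comp.significant == printed_significant


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d_combined(5.0, 2.0, 10, 5.0, 7.0, 12) == 0.0

    @pytest.mark.parametrize(
        "farm, expected",
        [("E", 1.53), ("A", 1.41)],
    )
    def test_reference_spot_values(self, farm, expected):
        m1, s1, m2, s2 = FIELD_STUDY_TABLE[farm]
        assert cohens_d_combined(m1, s1, 24, m2, s2, 24) == pytest.approx(
            expected, abs=0.01
        )

    def test_whole_reference_column(self):
        # at printed precision; farm T's published value is anomalous
        # relative to its own printed inputs under every standard convention
        for farm, (m1, s1, m2, s2) in FIELD_STUDY_TABLE.items():
            d = round(cohens_d_combined(m1, s1, 24, m2, s2, 24), 1)
            assert d == pytest.approx(FIELD_STUDY_COHENS_D[farm], abs=0.1)

    def test_combined_sd_matches_pooled_sample_oracle(self, rng):
        # reconstruct two groups with those exact moments and compare against
        # the SD of their concatenation (population denominator)
        for _ in range(10):
            x1 = rng.normal(10, 3, size=8)
            x2 = rng.normal(14, 5, size=12)
            m1, s1 = x1.mean(), x1.std(ddof=0)
            m2, s2 = x2.mean(), x2.std(ddof=0)
            combined_sd = np.concatenate([x1, x2]).std(ddof=0)
            d = cohens_d_combined(m1, s1, len(x1), m2, s2, len(x2))
            assert d == pytest.approx(abs(m1 - m2) / combined_sd, rel=1e-10)

    def test_zero_variance_cases(self):
        assert cohens_d_combined(1.0, 0.0, 5, 1.0, 0.0, 5) == 0.0
        # unequal means always contribute between-group spread to the
        # combined denominator, so d stays finite: |1-2| / 0.5
        assert cohens_d_combined(1.0, 0.0, 5, 2.0, 0.0, 5) == pytest.approx(2.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cohens_d_combined(1.0, -1.0, 5, 2.0, 1.0, 5)
        with pytest.raises(ValueError):
            cohens_d_combined(1.0, 1.0, 1, 2.0, 1.0, 5)


class TestMeanSdRegression:
    def test_proportional_gives_r_one(self):
        summaries = [
            BatchSummary("F", str(i), 10, float(m), 0.3 * m)
            for i, m in enumerate((10, 20, 30, 40))
        ]
        assert mean_sd_regression(summaries)["pearson_r"] == pytest.approx(1.0)

    def test_reference_table_correlation(self):
        r = mean_sd_regression(field_study_summaries())["pearson_r"]
        assert r == pytest.approx(0.83, abs=0.02)

    def test_matches_direct_formula_oracle(self, rng):
        means = rng.uniform(10, 50, size=10)
        sds = 0.2 * means + rng.normal(0, 2, size=10)
        summaries = [
            BatchSummary("F", str(i), 24, float(m), float(s))
            for i, (m, s) in enumerate(zip(means, sds))
        ]
        result = mean_sd_regression(summaries)
        cov = np.mean((means - means.mean()) * (sds - sds.mean()))
        r_direct = cov / (means.std() * sds.std())
        assert result["pearson_r"] == pytest.approx(r_direct, rel=1e-10)
        assert result["slope"] == pytest.approx(cov / means.var(), rel=1e-10)

    def test_degenerate_means(self):
        summaries = [BatchSummary("F", str(i), 10, 5.0, float(i + 1)) for i in range(4)]
        with pytest.raises(DegenerateDataError):
            mean_sd_regression(summaries)

    def test_needs_three_batches(self):
        with pytest.raises(ValueError):
            mean_sd_regression([BatchSummary("F", "1", 10, 5.0, 1.0)] * 2)
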