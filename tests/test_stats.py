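import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmri import (
    ContractError,
    DegenerateInputError,
    age_regression,
    bonferroni,
    cohens_d,
    corr_diff_test,
    generate_cohort,
    median_split_analysis,
    run_cohort_analysis,
    study_config,
    subjects_to_covariates,
    true_params_frame,
    two_sample_t,
)


class TestTwoSampleT:
    def test_identical_groups(self):
        gc = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gc.t == 0.0 and gc.p == 1.0 and gc.d == 0.0

    def test_closed_form_oracle(self):
        """Hand-computed pooled t for {0,0,1,1} vs {1,1,2,2}: t = -sqrt(6), df = 6."""
        gc = two_sample_t([0, 0, 1, 1], [1, 1, 2, 2])
        assert gc.t == pytest.approx(-np.sqrt(6.0), rel=1e-12)
        assert gc.df == 6
        assert gc.p == pytest.approx(0.04982526278057676, rel=1e-9)
        assert gc.d == pytest.approx(-np.sqrt(3.0), rel=1e-12)

    def test_d_sign_follows_t(self):
        gc = two_sample_t([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert gc.t > 0 and gc.d > 0

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0])

    def test_null_p_uniform(self):
        """Under the null, pooled-t p-values are uniform (KS test at alpha = .01)."""
        from scipy import stats as sps

        rng = np.random.default_rng(77)
        ps = [
            two_sample_t(rng.normal(size=12), rng.normal(size=12)).p
            for _ in range(2000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCohensD:
    def test_published_genu_effect_size(self):
        """Patients 4.1±1.1 vs controls 5.2±0.8 (x1e-2 scale) give d = 1.14."""
        assert cohens_d(4.1, 1.1, 5.2, 0.8, 26, 26) == pytest.approx(1.14, abs=5e-3)

    def test_zero_and_unit_effects(self):
        assert cohens_d(3.0, 1.0, 3.0, 2.0, 10, 10) == 0.0
        s = 0.8
        assert cohens_d(1.0, s, 1.0 + s, s, 10, 10) == pytest.approx(1.0)

    def test_unequal_n_uses_weighted_pooling(self):
        d = cohens_d(0.0, 1.0, 1.0, 2.0, 3, 21)
        pooled = np.sqrt((2 * 1.0 + 20 * 4.0) / 22)
        assert d == pytest.approx(1.0 / pooled)

    def test_both_sds_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cohens_d(1.0, 0.0, 2.0, 0.0, 5, 5)

    @settings(derandomize=True, max_examples=50)
    @given(
        m1=st.floats(-5, 5), m2=st.floats(-5, 5),
        s1=st.floats(0.1, 3), s2=st.floats(0.1, 3),
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
    )
    def test_antisymmetry_and_affine_invariance(self, m1, m2, s1, s2, a, b):
        d = cohens_d(m1, s1, m2, s2, 10, 10)
        assert cohens_d(m2, s2, m1, s1, 10, 10) == pytest.approx(-d, rel=1e-9, abs=1e-12)
        scaled = cohens_d(a * m1 + b, a * s1, a * m2 + b, a * s2, 10, 10)
        assert scaled == pytest.approx(d, rel=1e-9, abs=1e-12)


class TestBonferroni:
    def test_family_of_twelve(self):
        adj = bonferroni([0.0001, 0.04, 1.0], 12)
        assert adj[0] == pytest.approx(0.0012)
        assert adj[1] == pytest.approx(0.48)
        assert adj[2] == 1.0
        assert adj[0] < 0.05 < adj[1]

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ContractError):
            bonferroni([0.1, 0.2, 0.3], 2)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjustment_is_monotone(self, ps):
        """Adjusting can never turn a non-significant raw p significant."""
        for raw, adj in zip(ps, bonferroni(ps, 12)):
            assert adj >= min(raw, 1.0) - 1e-15
            if raw >= 0.05:
                assert adj >= 0.05


class TestAgeRegression:
    def test_exact_line(self):
        age = np.array([20.0, 30.0, 40.0, 50.0])
        rr = age_regression(age, 2 * age)
        assert rr.slope == pytest.approx(2.0) and rr.r == pytest.approx(1.0)
        assert rr.p < 1e-10

    def test_zero_age_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            age_regression([30.0, 30.0, 30.0], [1.0, 2.0, 3.0])

    def test_null_p_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        ps = []
        for _ in range(1000):
            age = rng.uniform(20, 61, 26)
            ps.append(age_regression(age, rng.normal(size=26)).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestCorrDiffTest:
    def test_equal_correlations(self):
        ct = corr_diff_test(0.5, 20, 0.5, 30)
        assert ct.z == 0.0 and ct.p == 1.0

    def test_published_genu_contrast_closed_form(self):
        """r = .72 vs .03 at n = 26/26 gives p ≈ .003 by the Fisher closed form."""
        ct = corr_diff_test(0.72, 26, 0.03, 26)
        assert ct.z == pytest.approx(2.9762084054757985, rel=1e-12)
        assert ct.p == pytest.approx(0.0029183646574542964, rel=1e-9)

    def test_p_decreases_with_n(self):
        ps = [corr_diff_test(0.6, n, 0.1, n).p for n in (10, 20, 40, 80)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_degenerate_r_rejected(self):
        with pytest.raises(ContractError):
            corr_diff_test(1.0, 20, 0.0, 20)


class TestMedianSplit:
    def _cohort_frame(self, n=52, seed=3, threshold_coupling=False):
        rng = np.random.default_rng(seed)
        pdi = rng.uniform(0.02, 0.06, n)
        if threshold_coupling:
            # FA tracks PDI only below the median of the PDI distribution
            fa = np.where(
                pdi < np.median(pdi), 0.55 + 4.0 * pdi, rng.normal(0.7, 0.03, n)
            )
            fa = fa + rng.normal(0, 0.005, n)
        else:
            fa = rng.normal(0.7, 0.03, n)
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "group": ["patient"] * (n // 2) + ["control"] * (n - n // 2),
                "age": rng.uniform(20, 61, n),
                "pdi": pdi,
                "fa": np.clip(fa, 0, 1),
            }
        )

    def test_even_split_of_52(self):
        ms = median_split_analysis(self._cohort_frame(), split_col="pdi")
        assert ms.n_lower == 26 and ms.n_upper == 26
        assert sum(ms.group_counts_lower.values()) == 26

    def test_odd_n_assigns_median_to_lower(self):
        ms = median_split_analysis(self._cohort_frame(n=51), split_col="pdi")
        assert ms.n_lower == 26 and ms.n_upper == 25

    def test_threshold_coupling_detected(self):
        """FA-PDI coupling restricted to low PDI shows up only in the lower half."""
        ms = median_split_analysis(
            self._cohort_frame(threshold_coupling=True), split_col="pdi"
        )
        assert ms.r_lower > 0.8
        assert abs(ms.r_upper) < 0.45
        assert ms.p_lower < 1e-4

    def test_all_identical_warning_path(self):
        df = self._cohort_frame()
        df["pdi"] = 0.04
        ms = median_split_analysis(df, split_col="pdi")
        assert ms.tie_warning is not None
        assert ms.n_upper == 0


@pytest.fixture(scope="module")
def small_cohort():
    cfg = study_config(n_per_group=10)
    coh = generate_cohort(cfg, seed=4, with_signals=False)
    fits = true_params_frame(coh.subjects)
    cov = subjects_to_covariates(coh.subjects)
    return fits, cov


class TestRunCohortAnalysis:
    def test_report_structure(self, small_cohort):
        fits, cov = small_cohort
        report = run_cohort_analysis(fits, cov)
        assert {"roi", "measure", "p", "cohens_d", "p_bonferroni"}.issubset(
            report.group_comparisons.columns
        )
        rois = set(report.group_comparisons["roi"])
        assert {"cc", "genu", "cingulate"}.issubset(rois)
        assert len(report.age_regressions)
        assert (report.correlations["analysis"] == "gm_wm_pdi").any()
        assert report.median_split is not None
        assert len(report.dose_correlations)

    def test_report_deterministic_bytes(self, small_cohort, tmp_path):
        """Identical inputs give byte-identical written reports."""
        fits, cov = small_cohort
        for d in ("a", "b"):
            run_cohort_analysis(fits, cov).to_csv(tmp_path / d)
        for name in (tmp_path / "a").iterdir():
            assert name.read_bytes() == (tmp_path / "b" / name.name).read_bytes()

    def test_missing_dose_is_skipped_not_fatal(self, small_cohort):
        fits, cov = small_cohort
        report = run_cohort_analysis(fits, cov.drop(columns=["dose"]))
        assert any("dose" in s for s in report.skipped)
        assert not len(report.dose_correlations)

    def test_summary_prints(self, small_cohort):
        fits, cov = small_cohort
        text = run_cohort_analysis(fits, cov).summary()
        assert "Group comparisons" in text and "Median split" in text
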