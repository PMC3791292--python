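import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmri import (
    CohortConfig,
    ConfigurationError,
    ContractError,
    DegenerateInputError,
    GroupROIParams,
    ROIGenParams,
    add_rician_noise,
    generate_cohort,
    study_config,
    synthesize_signal,
    true_params_frame,
    two_sample_t,
)
from conftest import TABLE_CC_PATIENT


def simple_config(n=26, snr=6.1, mu_sd=0.03, du_sd=0.2e-3, dr_sd=1.5e-5,
                  dr_means=(7.1e-5, 8.4e-5), fa=None, r=None, slope=0.0):
    groups = {
        "patient": GroupROIParams(mu=(0.55, mu_sd), du=(1.8e-3, du_sd),
                                  dr=(dr_means[0], dr_sd), fa=fa, fa_pdi_corr=r,
                                  pdi_age_slope=slope),
        "control": GroupROIParams(mu=(0.55, mu_sd), du=(1.8e-3, du_sd),
                                  dr=(dr_means[1], dr_sd), fa=fa, fa_pdi_corr=r,
                                  pdi_age_slope=slope),
    }
    return CohortConfig(
        group_sizes={"patient": n, "control": n},
        rois={"cc": ROIGenParams(groups=groups)},
        snr=snr, snr_reference_roi="cc", bmi=None,
    )


class TestSynthesizeSignal:
    def test_mu_one_is_pure_mono(self, protocol_shells):
        sig = synthesize_signal((1.0, 1.0, 2e-3, 5e-5), protocol_shells)
        np.testing.assert_allclose(sig, np.exp(-protocol_shells.b_values * 2e-3))

    def test_closed_form_half_mix(self, protocol_shells):
        b = protocol_shells.b_values
        sig = synthesize_signal((1.0, 0.5, 2e-3, 0.0), protocol_shells)
        k = int(np.flatnonzero(b == 1000)[0])
        assert sig[k] == pytest.approx(0.5 * np.exp(-2.0) + 0.5, rel=1e-12)

    def test_patient_curve_decreasing_with_expected_ratio(self, protocol_shells):
        """Direct evaluation of the two-compartment curve at the printed shells."""
        sig = synthesize_signal(TABLE_CC_PATIENT, protocol_shells)
        assert np.all(np.diff(sig) < 0)
        b = protocol_shells.b_values
        s0, mu, du, dr = TABLE_CC_PATIENT

        def S(b):
            return s0 * (mu * np.exp(-b * du) + (1 - mu) * np.exp(-b * dr))

        assert sig[-1] / sig[np.flatnonzero(b == 250)[0]] == pytest.approx(
            S(3800) / S(250), rel=1e-12
        )

    @settings(derandomize=True, max_examples=40)
    @given(
        mu=st.floats(0.05, 1.0),
        du=st.floats(1e-4, 5e-3),
        dr_frac=st.floats(0.0, 1.0),
    )
    def test_positive_strictly_decreasing(self, protocol_shells, mu, du, dr_frac):
        """Noiseless signal is positive and strictly decreasing in b for Du > 0."""
        sig = synthesize_signal((1.0, mu, du, dr_frac * du), protocol_shells)
        assert np.all(sig > 0)
        assert np.all(np.diff(sig) < 0)

    def test_per_direction_replicates_shell_value(self, protocol_shells):
        per_dir = synthesize_signal(TABLE_CC_PATIENT, protocol_shells, mode="per-direction")
        per_shell = synthesize_signal(TABLE_CC_PATIENT, protocol_shells)
        for val, shell in zip(per_shell, protocol_shells):
            np.testing.assert_array_equal(per_dir[shell.volumes], val)

    def test_invalid_params_rejected(self, protocol_shells):
        with pytest.raises(ContractError):
            synthesize_signal((1.0, 1.5, 2e-3, 5e-5), protocol_shells)
        with pytest.raises(ContractError):
            synthesize_signal((1.0, 0.5, 1e-5, 2e-3), protocol_shells)


class TestRicianNoise:
    def test_sigma_zero_identity(self):
        x = np.linspace(0, 1, 10)
        np.testing.assert_array_equal(add_rician_noise(x, 0.0, 1), x)

    def test_zero_signal_rayleigh_mean(self):
        """At zero signal the Rician reduces to Rayleigh with mean sigma*sqrt(pi/2)."""
        sigma = 0.3
        out = add_rician_noise(np.zeros(200_000), sigma, 42)
        assert out.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_seed_determinism(self):
        x = np.linspace(0.1, 1, 50)
        a = add_rician_noise(x, 0.2, 7)
        b = add_rician_noise(x, 0.2, 7)
        np.testing.assert_array_equal(a, b)


class TestGenerateCohort:
    def test_seed_determinism_full_chain(self):
        cfg = simple_config(n=4)
        a = generate_cohort(cfg, seed=5)
        b = generate_cohort(cfg, seed=5)
        assert a.subjects == b.subjects
        assert a.signals.frame.equals(b.signals.frame)

    def test_group_means_match_config_within_3se(self):
        """Drawn Mu/Du/Dr sample means converge to the configured means (CLT bound)."""
        cfg = simple_config(n=26)
        coh = generate_cohort(cfg, seed=12, with_signals=False)
        frame = true_params_frame(coh.subjects)
        frame["group"] = [s.split("-")[0] for s in frame["subject"]]
        for group, dr_mean in (("patient", 7.1e-5), ("control", 8.4e-5)):
            sub = frame[frame["group"] == group]
            for col, mean, sd in (
                ("mu", 0.55, 0.03),
                ("du", 1.8e-3, 0.2e-3),
                ("dr", dr_mean, 1.5e-5),
            ):
                se = sd / np.sqrt(len(sub))
                assert abs(sub[col].mean() - mean) < 3 * se, (group, col)

    def test_degenerate_zero_variance_cohort(self):
        """Zero SDs + zero noise: all subjects identical; the t-test flags degeneracy."""
        cfg = simple_config(n=5, snr=None, mu_sd=0.0, du_sd=0.0, dr_sd=0.0,
                            dr_means=(7.1e-5, 7.1e-5))
        coh = generate_cohort(cfg, seed=1, with_signals=False)
        frame = true_params_frame(coh.subjects)
        assert frame["pdi"].nunique() == 1
        pat = frame[frame["subject"].str.startswith("patient")]["pdi"]
        con = frame[frame["subject"].str.startswith("control")]["pdi"]
        with pytest.raises(DegenerateInputError):
            two_sample_t(pat, con)

    def test_fa_pdi_correlation_recovered(self):
        """Configured FA-PDI correlation lands within Fisher-z error of the target."""
        r_target = 0.67
        n = 400
        cfg = simple_config(n=n, fa=(0.7, 0.03), r=r_target)
        coh = generate_cohort(cfg, seed=9, with_signals=False)
        frame = true_params_frame(coh.subjects)
        pat = frame[frame["subject"].str.startswith("patient")]
        r_hat = np.corrcoef(pat["pdi"], pat["fa"])[0, 1]
        fisher_se = 1 / np.sqrt(n - 3)
        assert abs(np.arctanh(r_hat) - np.arctanh(r_target)) < 3 * fisher_se

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ConfigurationError):
            simple_config(fa=(0.7, 0.03), r=1.5).validate()

    def test_noiseless_pipeline_recovers_truth(self, protocol_shells):
        """With sigma -> 0 the fit pipeline returns the drawn parameters (1e-6 rel)."""
        from pdmri import fit_cohort

        cfg = simple_config(n=2, snr=None)
        coh = generate_cohort(cfg, seed=3)
        fits = fit_cohort(coh)
        truth = true_params_frame(coh.subjects)
        merged = fits.merge(truth, on=["subject", "roi"], suffixes=("_fit", "_true"))
        for col in ("mu", "du", "dr"):
            rel = np.abs(merged[f"{col}_fit"] - merged[f"{col}_true"]) / merged[f"{col}_true"]
            assert rel.max() < 1e-6, col

    def test_study_config_structure(self):
        cfg = study_config()
        cfg.validate()
        assert cfg.group_sizes == {"patient": 26, "control": 26}
        assert set(cfg.rois) == {"cc", "genu", "body", "splenium", "cingulate", "csf"}
        assert cfg.rois["csf"].mono
        coh = generate_cohort(cfg, seed=0, with_signals=False)
        assert len(coh.subjects) == 52

    def test_config_yaml_roundtrip(self):
        import yaml

        from pdmri.simulate import config_from_dict, config_to_dict

        cfg = study_config()
        d = yaml.safe_load(yaml.safe_dump(config_to_dict(cfg)))
        cfg2 = config_from_dict(d)
        a = generate_cohort(cfg, seed=2, with_signals=False)
        b = generate_cohort(cfg2, seed=2, with_signals=False)
        assert a.subjects == b.subjects
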