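"""Virtual-population tests: classifiers, eligibility, regimen, sampling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import adcpk
from adcpk import (
    ConfigurationError,
    InputError,
    PopulationConfig,
    apply_eligibility,
    build_regimen,
    classify_hepatic_nci,
    classify_renal,
    cockcroft_gault,
    sample_covariates,
    simulate_dataset,
)


class TestCockcroftGault:
    def test_hand_computed_male(self):
        assert cockcroft_gault(60, 70, 1.0, "male") == pytest.approx(77.78, abs=0.01)

    def test_female_scaling(self):
        male = cockcroft_gault(60, 70, 1.0, "male")
        female = cockcroft_gault(60, 70, 1.0, "female")
        assert female == pytest.approx(0.85 * male, rel=1e-12)
        assert female == pytest.approx(66.11, abs=0.01)

    def test_age_boundary_rejected(self):
        with pytest.raises(InputError):
            cockcroft_gault(140, 70, 1.0, "male")


class TestHepaticClassifier:
    @pytest.mark.parametrize("ast,bili,expected", [
        (0.8, 0.9, "normal"),
        (0.8, 1.2, "mild"),      # B1: elevated bilirubin
        (1.5, 0.9, "mild"),      # B2: elevated AST, normal bilirubin
        (0.8, 2.0, "moderate"),
        (0.8, 3.5, "severe"),
        (1.0, 1.0, "normal"),    # boundary: exactly ULN is normal
        (0.8, 1.5, "mild"),      # boundary: (1, 1.5] is mild
        (0.8, 3.0, "moderate"),  # boundary: (1.5, 3] is moderate
    ])
    def test_band_assignment(self, ast, bili, expected):
        assert classify_hepatic_nci(ast, bili) == expected

    @given(ast=st.floats(0, 10), bili=st.floats(0, 10))
    def test_total_on_nonnegative_reals(self, ast, bili):
        assert classify_hepatic_nci(ast, bili) in (
            "normal", "mild", "moderate", "severe")


class TestRenalClassifier:
    @pytest.mark.parametrize("crcl,expected", [
        (95, "normal"), (90, "normal"), (89.9, "mild"), (60, "mild"),
        (59.9, "moderate"), (30, "moderate"), (29.9, "severe"), (15, "severe"),
        (14.9, "esrd"), (0, "esrd"),
    ])
    def test_band_assignment(self, crcl, expected):
        assert classify_renal(crcl) == expected

    @given(crcl=st.floats(0, 300))
    def test_bands_partition_the_range(self, crcl):
        assert classify_renal(crcl) in ("normal", "mild", "moderate",
                                        "severe", "esrd")


class TestEligibility:
    def test_transaminase_exclusion(self, reference_covs):
        cov = reference_covs.with_updates(ast_xuln=2.6)
        included, reason = apply_eligibility(cov)
        assert not included and "hepatic" in reason

    def test_renal_exclusion(self, reference_covs):
        cov = reference_covs.with_updates(crcl=39.0)
        included, reason = apply_eligibility(cov)
        assert not included and "renal" in reason

    def test_normal_labs_included(self, reference_covs):
        cov = reference_covs.with_updates(ast_xuln=1.0, alt_xuln=1.0,
                                          bili_xuln=1.0, crcl=80.0)
        included, reason = apply_eligibility(cov)
        assert included and reason == ""

    def test_bilirubin_boundary_excludes(self, reference_covs):
        cov = reference_covs.with_updates(bili_xuln=1.5)
        assert not apply_eligibility(cov)[0]

    def test_missing_lab_raises(self, reference_covs):
        cov = reference_covs.with_updates(crcl=float("nan"))
        with pytest.raises(InputError, match="missing"):
            apply_eligibility(cov)


class TestRegimen:
    def test_default_regimen_arithmetic(self):
        doses = build_regimen(75.0)
        assert len(doses) == 6
        assert [d.time for d in doses] == [0, 21, 42, 63, 84, 105]
        assert all(d.amount == pytest.approx(135.0) for d in doses)
        assert all(d.duration == pytest.approx(90 / 1440) for d in doses)

    def test_single_cycle(self):
        doses = build_regimen(75.0, n_cycles=1)
        assert len(doses) == 1 and doses[0].time == 0.0

    def test_dose_scales_with_bodyweight(self):
        assert build_regimen(100.0)[0].amount == pytest.approx(180.0)


class TestSampleCovariates:
    def test_deterministic_given_seed(self):
        a = sample_covariates(30, seed=7)
        b = sample_covariates(30, seed=7)
        assert a == b

    def test_male_fraction_near_study_proportion(self):
        covs = sample_covariates(460, seed=42)
        frac = np.mean([c.sex == "male" for c in covs])
        assert abs(frac - 272 / 460) < 0.04

    def test_crcl_consistent_with_formula_and_band(self):
        for cov in sample_covariates(100, seed=8):
            assert cov.crcl == pytest.approx(cockcroft_gault(
                cov.age, cov.bodyweight, cov.serum_creatinine, cov.sex))
            assert cov.renal_category == classify_renal(cov.crcl)

    def test_hepatic_labs_consistent_with_category(self):
        for cov in sample_covariates(200, seed=9):
            assert classify_hepatic_nci(cov.ast_xuln, cov.bili_xuln) == \
                cov.hepatic_category

    def test_bodyweight_and_age_within_configured_ranges(self):
        cfg = PopulationConfig()
        for cov in sample_covariates(200, cfg, seed=10):
            assert cfg.bw_range[0] <= cov.bodyweight <= cfg.bw_range[1]
            assert cfg.age_range[0] <= cov.age <= cfg.age_range[1]

    def test_degenerate_config_gives_fully_specified_record(self):
        cfg = PopulationConfig(
            p_male=1.0, bw_median_male=80.0, bw_sdlog=0.0, age_mean=60.0,
            age_sd=0.0, p_hepatic_mild=0.0, p_hepatic_moderate=0.0,
            albumin_sd=0.0, scr_sdlog=0.0, bcell_sdlog=0.0, spd_sdlog=0.0,
            p_ecog_ge1=1.0, p_treatment_naive=0.0, p_combo_rg=1.0,
            p_combo_benda=0.0)
        (cov,) = sample_covariates(1, cfg, seed=1)
        assert cov.sex == "male" and cov.bodyweight == pytest.approx(80.0)
        assert cov.age == pytest.approx(60.0)
        assert cov.hepatic_category == "normal"
        assert cov.albumin == pytest.approx(39.0)
        assert cov.ecog == 1 and cov.combo_rg and not cov.combo_benda

    def test_hepatic_patients_have_lower_albumin_on_average(self):
        cfg = PopulationConfig(p_hepatic_mild=0.5)
        covs = sample_covariates(600, cfg, seed=11)
        alb_norm = np.mean([c.albumin for c in covs
                            if c.hepatic_category == "normal"])
        alb_imp = np.mean([c.albumin for c in covs
                           if c.hepatic_category != "normal"])
        assert alb_imp < alb_norm - 2.0

    def test_infeasible_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            PopulationConfig(p_hepatic_mild=0.7, p_hepatic_moderate=0.5)


class TestSimulateDataset:
    def test_noise_free_observations_equal_predictions(self, model):
        quiet = model.with_updates(sigma={"acmmae": 1e-30, "mmae": 1e-30})
        covs = sample_covariates(2, seed=12)
        pats = simulate_dataset(quiet, covs, schedule="rich", seed=13)
        pat = pats[0]
        times = np.unique([o.time for o in pat.observations])
        params = adcpk.apply_covariates(quiet, pat.covariates, pat.true_etas)
        conc = adcpk.simulate_profile(params, pat.doses, times, quiet.dose_conv)
        for o in pat.observations:
            if o.censored:
                continue
            row = adcpk.ANALYTES.index(o.analyte)
            col = np.searchsorted(times, o.time)
            assert o.concentration == pytest.approx(conc[row, col], rel=1e-9)

    def test_raised_lloq_censors_everything(self, model):
        covs = sample_covariates(3, seed=14)
        pats = simulate_dataset(model, covs, schedule="sparse", seed=15,
                                lloq={"acmmae": 0.359, "mmae": 1e9})
        mmae = [o for p in pats for o in p.observations if o.analyte == "mmae"]
        assert mmae and all(o.censored for o in mmae)

    def test_blq_fraction_higher_for_payload_analyte(self, model):
        covs = sample_covariates(50, seed=16)
        pats = simulate_dataset(model, covs, schedule="rich", seed=17)
        obs = [o for p in pats for o in p.observations]
        frac = {a: np.mean([o.censored for o in obs if o.analyte == a])
                for a in adcpk.ANALYTES}
        assert frac["mmae"] > frac["acmmae"]

    def test_censoring_monotone_in_lloq(self, model):
        covs = sample_covariates(5, seed=18)
        low = simulate_dataset(model, covs, schedule="rich", seed=19)
        covs2 = sample_covariates(5, seed=18)
        high = simulate_dataset(model, covs2, schedule="rich", seed=19,
                                lloq={"acmmae": 3.59, "mmae": 0.359})
        for plo, phi in zip(low, high):
            for olo, ohi in zip(plo.observations, phi.observations):
                if olo.censored:
                    assert ohi.censored

    def test_singular_omega_rejected(self, model):
        singular = model.with_updates(omega=np.zeros((5, 5)))
        with pytest.raises(ConfigurationError, match="singular"):
            simulate_dataset(singular, sample_covariates(1, seed=20), seed=21)

    def test_truth_stored_and_reproducible(self, model):
        covs = sample_covariates(3, seed=22)
        a = simulate_dataset(model, covs, schedule="sparse", seed=23)
        b = simulate_dataset(model, sample_covariates(3, seed=22),
                             schedule="sparse", seed=23)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.true_etas, pb.true_etas)
            assert pa.observations == pb.observations
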