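"""Structural/covariate model unit tests: covariate algebra, solver oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

import adcpk
from adcpk import (
    ConfigurationError,
    CovariateEffect,
    DoseEvent,
    InputError,
    SolverError,
    apply_covariates,
    simulate_profile,
)
from adcpk.model import PARAM_NAMES


@pytest.fixture()
def model_reference_covs(reference_covs):
    """The model-coding reference patient: every flag at its inactive level.

    (The correction reference record intentionally differs: it sets the
    anti-CD20 combination *active*, which is an effect-carrying level.)
    """
    return reference_covs.with_updates(combo_rg=False)


class TestApplyCovariates:
    def test_reference_patient_identity(self, model, model_reference_covs):
        params = apply_covariates(model, model_reference_covs, etas=None)
        for name in PARAM_NAMES:
            assert getattr(params, name) == pytest.approx(
                getattr(model, f"{name}_ref"), rel=1e-12), name

    def test_bodyweight_power_term(self, model, model_reference_covs):
        heavy = model_reference_covs.with_updates(bodyweight=150.0)
        params = apply_covariates(model, heavy)
        # 150 kg vs 75 kg reference with exponent 0.73 on conjugate clearance
        assert params.cl_inf / model.cl_inf_ref == pytest.approx(2**0.73, rel=1e-12)
        assert 2**0.73 == pytest.approx(1.659, abs=5e-4)

    def test_hepatic_impairment_shifts_formation_fraction(self, model,
                                                          model_reference_covs):
        impaired = model_reference_covs.with_updates(hepatic_category="mild",
                                                     bili_xuln=1.2)
        params = apply_covariates(model, impaired)
        assert params.frac_ns / model.frac_ns_ref == pytest.approx(1.19, rel=1e-12)

    def test_frozen_covariate_contributes_reference_multiplier(self, model,
                                                               model_reference_covs):
        heavy = model_reference_covs.with_updates(bodyweight=150.0)
        params = apply_covariates(model, heavy, frozen={"bodyweight"})
        assert params.cl_inf == pytest.approx(model.cl_inf_ref, rel=1e-12)

    def test_unknown_frozen_name_rejected(self, model, reference_covs):
        with pytest.raises(ConfigurationError, match="frozen"):
            apply_covariates(model, reference_covs, frozen={"no_such_covariate"})

    def test_nonpositive_continuous_covariate_rejected(self, model, reference_covs):
        bad = reference_covs.with_updates(albumin=-1.0)
        with pytest.raises(InputError):
            apply_covariates(model, bad)

    def test_frac_ns_clipped_with_warning(self, model, reference_covs):
        etas = np.zeros(5)
        etas[3] = 3.0  # e^3 * 0.14 > 1
        with pytest.warns(UserWarning, match="frac_ns"):
            params = apply_covariates(model, reference_covs, etas)
        assert params.frac_ns == 1.0

    def test_multiplicative_composition_is_order_independent(self, model,
                                                             reference_covs):
        shuffled = model.with_updates(
            covariate_effects=tuple(reversed(model.covariate_effects)))
        covs = reference_covs.with_updates(bodyweight=110.0, albumin=30.0,
                                           sex="male", combo_rg=False)
        a = apply_covariates(model, covs)
        b = apply_covariates(shuffled, covs)
        for name in PARAM_NAMES:
            assert getattr(a, name) == pytest.approx(getattr(b, name), rel=1e-14)

    @given(weight=st.floats(40.0, 145.0))
    def test_power_multiplier_matches_closed_form(self, weight):
        eff = CovariateEffect("cl_inf", "bodyweight", "power", 0.73, 75.0)
        assert eff.multiplier(weight) == pytest.approx((weight / 75.0) ** 0.73)


class TestSimulateProfile:
    def test_zero_dose_gives_zero_concentrations(self, model, reference_covs):
        params = model.reference_parameters()
        doses = [DoseEvent(0.0, 0.0, 90 / 1440)]
        conc = simulate_profile(params, doses, np.linspace(0, 42, 50),
                                model.dose_conv)
        assert np.all(conc == 0.0)

    def test_linearity_in_dose(self, model, standard_regimen):
        params = model.reference_parameters()
        times = np.linspace(0.05, 126, 80)
        c1 = simulate_profile(params, standard_regimen, times, model.dose_conv)
        doubled = [DoseEvent(d.time, 2 * d.amount, d.duration)
                   for d in standard_regimen]
        c2 = simulate_profile(params, doubled, times, model.dose_conv)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-9)

    def test_zero_before_first_dose(self, model):
        params = model.reference_parameters()
        doses = [DoseEvent(10.0, 135.0, 90 / 1440)]
        conc = simulate_profile(params, doses, np.array([0.0, 5.0, 9.9, 12.0]),
                                model.dose_conv)
        assert np.all(conc[:, :3] == 0.0)
        assert np.all(conc[:, 3] > 0.0)

    def test_one_compartment_closed_form(self, model):
        # q -> 0, cl_t = 0, near-instantaneous dose: amounts follow
        # (D * dose_conv / v1) * exp(-(cl_inf / v1) * t)
        p = adcpk.IndividualParameters(
            cl_inf=0.9, cl_t=0.0, k_des=0.1, v1=3.0, q=1e-12, v2=3.0,
            frac_ns=0.1, cl_m=15.0, v_m=45.0)
        dose = [DoseEvent(0.0, 100.0, 1e-6)]
        t = np.linspace(0.5, 40, 40)
        conc = simulate_profile(p, dose, t, 10.0)
        expected = (100.0 * 10.0 / 3.0) * np.exp(-(0.9 / 3.0) * t)
        np.testing.assert_allclose(conc[0], expected, rtol=1e-3)

    def test_against_scipy_ivp_oracle(self, model, standard_regimen):
        """Independent adaptive-solver cross-check of the full model."""
        p = model.reference_parameters()
        k_m = p.cl_m / p.v_m
        d = standard_regimen[0]

        def rhs(t, a):
            rate = sum(dd.amount * model.dose_conv / dd.duration
                       for dd in standard_regimen
                       if dd.time < t < dd.time + dd.duration)
            cl = p.cl_inf + p.cl_t * np.exp(-p.k_des * t)
            c_ac = a[0] / p.v1
            return [rate - (cl + p.q) * c_ac + p.q / p.v2 * a[1],
                    p.q * c_ac - p.q / p.v2 * a[1],
                    p.frac_ns * cl * c_ac - k_m * a[2]]

        times = np.array([0.5, 2.0, 10.0, 20.9, 44.0, 108.0, 125.0])
        # small max_step so the adaptive solver cannot step over an infusion
        sol = solve_ivp(rhs, (0, 126), [0, 0, 0], t_eval=times, rtol=1e-10,
                        atol=1e-8, max_step=0.02, method="LSODA")
        ours = simulate_profile(p, standard_regimen, times, model.dose_conv)
        np.testing.assert_allclose(ours[0], sol.y[0] / p.v1, rtol=1e-3)
        np.testing.assert_allclose(ours[1], sol.y[2] / p.v_m, rtol=1e-3)

    def test_superposition_of_single_doses(self, model, standard_regimen):
        """Linear time-varying system: the multi-dose solution equals the sum
        of single-dose solutions on the shared absolute clock."""
        p = model.reference_parameters()
        times = np.linspace(0.1, 126, 60)
        full = simulate_profile(p, standard_regimen, times, model.dose_conv)
        total = np.zeros_like(full)
        for d in standard_regimen:
            total += simulate_profile(p, [d], times, model.dose_conv)
        np.testing.assert_allclose(full, total, rtol=1e-8, atol=1e-12)

    def test_time_invariance_without_clearance_decay(self, model):
        """cl_t = 0 removes the time dependence: a shifted dose gives a
        shifted profile."""
        p = adcpk.IndividualParameters(
            cl_inf=0.9, cl_t=0.0, k_des=0.1, v1=3.2, q=0.55, v2=3.0,
            frac_ns=0.14, cl_m=15.0, v_m=45.0)
        offsets = np.array([0.25, 1.0, 5.0, 15.0])
        c0 = simulate_profile(p, [DoseEvent(0.0, 135.0, 90 / 1440)],
                              offsets, model.dose_conv)
        c1 = simulate_profile(p, [DoseEvent(21.0, 135.0, 90 / 1440)],
                              21.0 + offsets, model.dose_conv)
        np.testing.assert_allclose(c0, c1, rtol=1e-9)

    def test_mmae_formation_limited_auc_identity(self, model, standard_regimen):
        """In the fast-elimination limit the payload AUC over an interval
        approaches frac_ns * integral(CL(t) * C_ac) / cl_m."""
        base = model.reference_parameters()
        fast = adcpk.IndividualParameters(
            cl_inf=base.cl_inf, cl_t=base.cl_t, k_des=base.k_des, v1=base.v1,
            q=base.q, v2=base.v2, frac_ns=base.frac_ns,
            cl_m=900.0, v_m=45.0)  # elimination half-life ~ 1 hour
        grid = np.arange(0.0, 126.0001, 0.005)
        conc = simulate_profile(fast, standard_regimen, grid, model.dose_conv)
        cl_t = fast.cl_inf + fast.cl_t * np.exp(-fast.k_des * grid)
        expected = fast.frac_ns * np.trapezoid(cl_t * conc[0], grid) / fast.cl_m
        actual = np.trapezoid(conc[1], grid)
        assert actual == pytest.approx(expected, rel=2e-3)

    def test_mmae_auc_small_fraction_of_conjugate(self, model, standard_regimen):
        """Typical-patient payload AUC is below 3% of the conjugate AUC."""
        p = model.reference_parameters()
        grid = np.arange(105.0, 126.0001, 0.01)
        conc = simulate_profile(p, standard_regimen, grid, model.dose_conv)
        auc = np.trapezoid(conc, grid, axis=1)
        assert auc[1] / auc[0] < 0.03

    def test_unsorted_times_rejected(self, model, standard_regimen):
        with pytest.raises(InputError):
            simulate_profile(model.reference_parameters(), standard_regimen,
                             np.array([2.0, 1.0]), model.dose_conv)

    def test_overlapping_infusions_rejected(self, model):
        doses = [DoseEvent(0.0, 100.0, 1.0), DoseEvent(0.5, 100.0, 1.0)]
        with pytest.raises(InputError, match="overlap"):
            simulate_profile(model.reference_parameters(), doses,
                             np.array([2.0]), model.dose_conv)

    def test_nonfinite_solution_raises(self, model, standard_regimen):
        # absurd elimination rate makes the fixed-step solution blow up
        p = adcpk.IndividualParameters(
            cl_inf=0.78, cl_t=0.3, k_des=0.12, v1=3.2, q=0.55, v2=3.0,
            frac_ns=0.14, cl_m=1e6, v_m=1.0)
        with pytest.raises(SolverError):
            simulate_profile(p, standard_regimen, np.array([20.0]),
                             model.dose_conv)


class TestModelValidation:
    def test_omega_must_be_psd(self, model):
        omega = np.diag([0.04, 0.02, 0.09, 0.12, 0.09]).copy()
        omega[0, 1] = omega[1, 0] = 1.0  # breaks PSD
        with pytest.raises(ConfigurationError, match="semi-definite"):
            model.with_updates(omega=omega)

    def test_frac_ns_reference_bounded(self, model):
        with pytest.raises(ConfigurationError):
            model.with_updates(frac_ns_ref=1.3)

    def test_unknown_effect_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            CovariateEffect("cl_inf", "bodyweight", "sigmoid", 1.0, 75.0)
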