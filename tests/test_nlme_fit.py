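"""Mixed-effects machinery: effect mapping, MAP objective, population fit."""

import dataclasses

import numpy as np
import pytest

from gadoflux import (
    Cohort,
    DoseProtocol,
    PhysiologicalConstants,
    UncertaintyConfig,
    default_population,
    fit_individual_map,
    fit_population,
    fit_sts,
    individual_parameter,
    leave_one_out_truncated_fit,
    neg_log_joint,
)
from gadoflux.errors import InsufficientDataError, ValidationError
from gadoflux.nlme_fit import OMEGA_FLOOR, ParameterDistribution, PopulationModel
from gadoflux.sts_fit import ObservationSet, OptimizerSettings
from gadoflux.synthetic_cohort import CohortSpec, generate_patient


def _population(omegas=(0.5, 0.5, 0.5, 0.5, 1.0)):
    return PopulationModel(
        (
            ParameterDistribution("k_diff", "lognormal", 1.7e-3, omegas[0]),
            ParameterDistribution("k_ph", "lognormal", 4.7e-3, omegas[1]),
            ParameterDistribution("k_hp", "lognormal", 28e-3, omegas[2]),
            ParameterDistribution("k_hb", "lognormal", 38e-3, omegas[3]),
            ParameterDistribution("xi", "normal", 1.6, omegas[4]),
        )
    )


class TestIndividualParameter:
    def test_zero_effect_returns_typical_value(self):
        for dist in _population():
            assert individual_parameter(dist, 0.0) == dist.theta

    def test_lognormal_doubling_effect(self):
        dist = ParameterDistribution("k_ph", "lognormal", 4.7e-3, 0.1)
        assert individual_parameter(dist, np.log(2)) == pytest.approx(9.4e-3, rel=1e-12)

    def test_normal_additive_effect(self):
        dist = ParameterDistribution("xi", "normal", 1.6, 1.0)
        assert individual_parameter(dist, -0.2) == pytest.approx(1.4, rel=1e-12)

    def test_strictly_monotone_in_eta(self):
        etas = np.linspace(-2, 2, 9)
        for dist in _population():
            vals = [individual_parameter(dist, e) for e in etas]
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_family_validation(self):
        with pytest.raises(ValidationError):
            ParameterDistribution("k_ph", "weibull", 1.0, 0.1)
        with pytest.raises(ValidationError):
            _population((0.5, 0.5, 0.5, 0.5, -1.0))


class TestNegLogJoint:
    def test_perfect_fit_zero_etas_leaves_log_omega_constant(
        self, noisefree_patient, constants, dose70
    ):
        pop = _population()
        cohort = Cohort([noisefree_patient])
        val = neg_log_joint({noisefree_patient.patient_id: np.zeros(5)}, pop, cohort,
                            constants, {noisefree_patient.patient_id: dose70})
        expected = np.sum(np.log(pop.omegas()))
        assert val == pytest.approx(expected, abs=1e-15)

    def test_single_observation_hand_assembled_value(self, constants, dose70,
                                                     typical_params):
        """Objective equals ½·Σ residual² /σ² + Σ η²/2ω² + Σ ln ω."""
        spec = CohortSpec(n_patients=1, stage_counts=(1, 0, 0, 0, 0), noise_sd=0.0,
                          schedule_s=(600.0,), seed=2)
        patient = generate_patient(typical_params, "F0", spec,
                                   np.random.default_rng(2), patient_id="ONE",
                                   body_weight=70.0)
        pop = _population()
        eta = np.array([0.1, -0.2, 0.05, 0.0, 0.3])
        params = pop.params_from_eta(eta)
        obs = ObservationSet(patient)
        liver, spleen = obs.predict(params, constants, dose70)
        expected = 0.5 * (
            ((liver[0] - patient.liver_dr1[0]) / 0.18) ** 2
            + ((spleen[0] - patient.spleen_dr1[0]) / 0.18) ** 2
        )
        expected += np.sum(eta**2 / (2 * pop.omegas() ** 2)) + np.sum(np.log(pop.omegas()))
        val = neg_log_joint({"ONE": eta}, pop, Cohort([patient]), constants,
                            {"ONE": dose70})
        assert val == pytest.approx(expected, abs=1e-12)

    def test_zero_omega_with_nonzero_eta_is_infinite(self, noisefree_patient,
                                                     constants, dose70):
        pop = _population((0.0, 0.5, 0.5, 0.5, 1.0))
        eta = np.array([0.1, 0, 0, 0, 0])
        val = neg_log_joint({noisefree_patient.patient_id: eta}, pop,
                            Cohort([noisefree_patient]), constants,
                            {noisefree_patient.patient_id: dose70})
        assert np.isinf(val) and val > 0

    def test_growing_eta_strictly_increases_objective_on_perfect_data(
        self, noisefree_patient, constants, dose70
    ):
        pop = _population()
        cohort = Cohort([noisefree_patient])
        doses = {noisefree_patient.patient_id: dose70}
        vals = [
            neg_log_joint({noisefree_patient.patient_id: np.array([e, 0, 0, 0, 0])},
                          pop, cohort, constants, doses)
            for e in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestFitIndividualMap:
    def test_uninformative_data_shrinks_to_typical_values(self, noisy_patient,
                                                          constants, dose70):
        config = UncertaintyConfig(sigma_floor=1e6)
        pop = _population()
        est = fit_individual_map(noisy_patient, pop, constants, dose70, config)
        assert np.linalg.norm(est.eta) < 1e-3
        assert est.params.k_ph == pytest.approx(4.7e-3, rel=1e-3)

    def test_wide_priors_converge_to_sts_estimate(self, constants, dose70):
        from gadoflux import RateParameters

        true = RateParameters(2.0e-3, 5.5e-3, 25e-3, 30e-3, 1.8)
        spec = CohortSpec(n_patients=1, stage_counts=(1, 0, 0, 0, 0), noise_sd=0.0,
                          seed=1)
        patient = generate_patient(true, "F0", spec, np.random.default_rng(1),
                                   body_weight=70.0)
        sts = fit_sts(patient, constants, dose70,
                      settings=OptimizerSettings(n_starts=3))
        pop = _population((20.0, 20.0, 20.0, 20.0, 50.0))
        est = fit_individual_map(patient, pop, constants, dose70)
        for name in ("k_diff", "k_ph", "k_hp", "k_hb", "xi"):
            assert getattr(est.params, name) == pytest.approx(
                getattr(sts.params, name), rel=0.02
            )

    def test_shrinkage_reduces_effect_norm(self, noisy_patient, constants, dose70):
        """MAP effects are closer to zero than the unpenalized optimum."""
        pop = _population((0.3, 0.3, 0.3, 0.3, 0.3))
        est = fit_individual_map(noisy_patient, pop, constants, dose70)
        sts = fit_sts(noisy_patient, constants, dose70,
                      settings=OptimizerSettings(n_starts=3))
        theta = pop.thetas()
        eta_sts = np.array([
            np.log(sts.params.k_diff / theta[0]),
            np.log(sts.params.k_ph / theta[1]),
            np.log(sts.params.k_hp / theta[2]),
            np.log(sts.params.k_hb / theta[3]),
            sts.params.xi - theta[4],
        ])
        assert np.linalg.norm(est.eta) < np.linalg.norm(eta_sts)


class TestFitPopulation:
    def test_identical_noisefree_patients_collapse_population(self, constants):
        from gadoflux import RateParameters

        true = RateParameters(2.0e-3, 6.0e-3, 25e-3, 30e-3, 1.9)
        spec = CohortSpec(n_patients=1, stage_counts=(1, 0, 0, 0, 0), noise_sd=0.0,
                          seed=9)
        base = generate_patient(true, "F0", spec, np.random.default_rng(9),
                                body_weight=70.0)
        cohort = Cohort([dataclasses.replace(base, patient_id=f"C{i}") for i in range(3)])
        fit = fit_population(cohort, init=_population(), max_iter=80)
        assert fit.converged
        assert np.all(fit.population.omegas() < 1e-6)
        # theta migrates from the healthy priors to the common individual optimum
        assert fit.population["k_ph"].theta == pytest.approx(true.k_ph, rel=0.02)
        assert fit.population["xi"].theta == pytest.approx(true.xi, rel=0.02)

    def test_objective_trace_non_increasing(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_population(cohort, max_iter=6)
        trace = fit.objective_trace
        assert len(trace) >= 2
        assert all(a >= b - 1e-6 * (1 + abs(a)) for a, b in zip(trace, trace[1:]))

    def test_estimates_reproducible_from_population_and_eta(self, small_cohort):
        cohort, _ = small_cohort
        fit = fit_population(cohort, max_iter=3)
        for est in fit.estimates:
            rebuilt = fit.population.params_from_eta(est.eta)
            assert rebuilt == est.params

    def test_single_patient_rejected_without_freeze(self, noisy_patient):
        with pytest.raises(ValidationError):
            fit_population(Cohort([noisy_patient]))

    def test_freeze_population_keeps_priors(self, small_cohort):
        cohort, _ = small_cohort
        init = _population()
        fit = fit_population(cohort, init=init, freeze_population=True)
        assert fit.population == init
        assert fit.converged


@pytest.fixture(scope="module")
def cohort_and_warm():
    spec = CohortSpec(n_patients=6, stage_counts=(6, 0, 0, 0, 0), seed=31)
    from gadoflux.synthetic_cohort import generate_cohort

    cohort, truth = generate_cohort(spec)
    warm = fit_population(cohort, max_iter=5)
    return cohort, warm


class TestLeaveOneOut:
    def test_infinite_cutoff_reproduces_full_data_estimate(self, cohort_and_warm):
        cohort, warm = cohort_and_warm
        pid = cohort.patients[0].patient_id
        est = leave_one_out_truncated_fit(cohort, pid, cutoff_s=np.inf, warm=warm)
        full = next(e for e in warm.estimates if e.patient_id == pid)
        assert est.params == full.params

    def test_truncated_estimate_returned_for_eligible_patient(self, cohort_and_warm):
        cohort, warm = cohort_and_warm
        pid = cohort.patients[1].patient_id
        est = leave_one_out_truncated_fit(cohort, pid, cutoff_s=600.0, warm=warm)
        assert est.patient_id == pid
        assert np.all(np.isfinite(est.eta))
        # GOF was computed on the truncated (<=10 min) observations only
        target = cohort.get(pid)
        n_est = int(np.sum((target.times >= 180.0) & (target.times <= 600.0)))
        assert est.gof.df == 2 * n_est

    def test_patient_without_late_data_rejected(self, cohort_and_warm):
        cohort, warm = cohort_and_warm
        short = cohort.patients[2].restrict(cohort.patients[2].times <= 600.0)
        patients = [short if p.patient_id == short.patient_id else p for p in cohort]
        modified = Cohort(patients)
        with pytest.raises(InsufficientDataError, match="after 600"):
            leave_one_out_truncated_fit(modified, short.patient_id, cutoff_s=600.0,
                                        warm=warm)

    def test_patient_without_estimation_window_rejected(self, cohort_and_warm):
        cohort, _ = cohort_and_warm
        late = cohort.patients[3].restrict(cohort.patients[3].times > 600.0)
        patients = [late if p.patient_id == late.patient_id else p for p in cohort]
        modified = Cohort(patients)
        with pytest.raises(InsufficientDataError, match="no usable observation"):
            leave_one_out_truncated_fit(modified, late.patient_id, cutoff_s=600.0)
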