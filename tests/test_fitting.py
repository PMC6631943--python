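"""Estimation: in-vitro Michaelis-Menten fits, empirical-Bayes conditional
modes, the importance-sampling EM, and the visual predictive check."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

import popivivc as pv
from popivivc import defaults
from popivivc.fitting import NonIdentifiableError


class TestInvitroFit:
    def test_noiseless_round_trip(self):
        p = defaults.invitro_params("IR")
        profs = pv.generate_invitro_dataset(p, noise_sd=0.0, seed=1, formulation_id="IR")
        fit = pv.fit_invitro_mm(profs)
        assert fit.estimates.vmax_invitro == pytest.approx(p.vmax_invitro, rel=1e-3)
        assert fit.estimates.am50_invitro == pytest.approx(p.am50_invitro, rel=1e-3)

    def test_noisy_recovery_within_five_percent(self):
        p = defaults.invitro_params("SR_fast")
        profs = pv.generate_invitro_dataset(p, noise_sd=1.0, seed=7, formulation_id="SR_fast")
        fit = pv.fit_invitro_mm(profs)
        assert fit.estimates.vmax_invitro == pytest.approx(p.vmax_invitro, rel=0.05)

    def test_percent_and_fraction_inputs_agree(self):
        p = defaults.invitro_params("SR_medium")
        profs = pv.generate_invitro_dataset(p, noise_sd=0.5, seed=3, formulation_id="SR_medium")
        as_frac = [
            pv.DissolutionProfile(
                q.formulation_id, q.ph_label, q.vessel_id, q.times, q.pct_dissolved / 100.0, q.dose
            )
            for q in profs
        ]
        a = pv.fit_invitro_mm(profs).estimates
        b = pv.fit_invitro_mm(as_frac).estimates
        assert a.vmax_invitro == pytest.approx(b.vmax_invitro, rel=1e-6)

    def test_joint_fit_resolves_fast_release_ridge(self):
        # per-formulation fits of the IR tablet are ridge-unidentifiable
        # (one pre-plateau sample); sharing am50 across formulations pins it
        profs = []
        for form in defaults.FORMULATIONS:
            profs += pv.generate_invitro_dataset(
                defaults.invitro_params(form), noise_sd=2.0, seed=11, formulation_id=form
            )
        fit = pv.fit_invitro_mm_joint(profs)
        for form in defaults.FORMULATIONS:
            assert fit.estimates[form].vmax_invitro == pytest.approx(
                defaults.VMAX_INVITRO[form], rel=0.15
            ), form
        assert fit.diagnostics["shared_am50"] == pytest.approx(defaults.AM50_INVITRO, rel=0.25)

    def test_flat_profile_not_identifiable(self):
        flat = [
            pv.DissolutionProfile("x", "1.2", "V1", defaults.DISSOLUTION_TIMES,
                                  np.zeros(14), 60.0)
        ]
        with pytest.raises(NonIdentifiableError):
            pv.fit_invitro_mm(flat)


class TestConditionalMode:
    def test_zero_variability_limit_returns_population_means(self, population, rk4_config):
        pop0 = replace(population, omega2={})
        prof = pv.simulate_pk(defaults.typical_subject("IR", "s1"), defaults.PLASMA_TIMES,
                              config=rk4_config)
        sp = pv.conditional_mode(prof, pop0)
        assert sp.disposition == defaults.DISPOSITION

    def test_recovers_known_individual_parameters(self, population, rk4_config):
        # subject deviating on three well-identified parameters, near-zero
        # residual noise: the joint mode must land on the generating values
        eta = {"cl": 0.3, "v1": -0.2, "vmax_invivo:IR": 0.25}
        pop = replace(
            population,
            omega2={k: 0.2 for k in eta},
            sigma=1e-4,
        )
        sp_true = pop.subject_parameters("IR", 20.0, "known", eta)
        prof = pv.simulate_pk(sp_true, defaults.PLASMA_TIMES, config=rk4_config)
        sp_hat = pv.conditional_mode(prof, pop)
        assert sp_hat.disposition.cl == pytest.approx(sp_true.disposition.cl, rel=0.01)
        assert sp_hat.disposition.v1 == pytest.approx(sp_true.disposition.v1, rel=0.01)
        assert sp_hat.dissolution.vmax_invivo == pytest.approx(
            sp_true.dissolution.vmax_invivo, rel=0.01
        )

    def test_empty_observations_rejected(self, population):
        blq = pv.PlasmaProfile(
            "empty", "IR", 20.0, np.array([1.0, 2.0, 3.0]), np.zeros(3),
            np.ones(3, dtype=bool),
        )
        with pytest.raises(ValueError):
            pv.conditional_mode(blq, population)


def _noiseless_cohort_and_init():
    """Cohort at the population means (no variability, negligible noise) and
    a mildly perturbed starting model; the Hill/steepness shape parameters
    are held fixed (not identifiable from 19-sample profiles)."""
    pop = defaults.reference_population()
    pop0 = replace(pop, omega2={}, sigma=1e-6)
    profiles, _ = pv.generate_cohort(pop0, seed=2)
    fix = frozenset({"imax", "hill_stomach", "hill_intestine"})
    rng = np.random.default_rng(0)
    init_theta = {
        k: (v if k in fix else v * float(np.exp(rng.normal(0, 0.2))))
        for k, v in pop.theta.items()
    }
    init = pv.PopulationModel(
        theta=init_theta,
        omega2={k: 0.1 for k in pop.theta if k not in fix},
        sigma=0.2,
    )
    return pop, profiles, init, fix


@pytest.fixture(scope="module")
def noiseless_fit():
    pop, profiles, init, fix = _noiseless_cohort_and_init()
    opts = pv.FitOptions(
        n_samples=150, max_iter=60, seed=3, fix=fix, rk4_step=0.02,
        tol=2e-3, tol_window=5, sigma_damping=0.6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pv.fit_popk(profiles, init, opts)
    return pop, fix, res


class TestPopulationFit:

    def test_noiseless_recovery_within_two_percent(self, noiseless_fit):
        pop, fix, res = noiseless_fit
        for k, truth in pop.theta.items():
            if k in fix:
                continue
            assert res.estimates.theta[k] == pytest.approx(truth, rel=0.02), k

    def test_residual_error_collapses_on_noiseless_data(self, noiseless_fit):
        _, _, res = noiseless_fit
        assert res.estimates.sigma < 1e-3

    def test_objective_non_decreasing_within_monte_carlo_error(self, noiseless_fit):
        _, _, res = noiseless_fit
        obj = np.array(res.objective)
        se = np.array(res.diagnostics["objective_se"])
        drops = obj[:-1] - obj[1:]
        allowed = 3.0 * np.sqrt(se[:-1] ** 2 + se[1:] ** 2) + 1e-6
        assert np.all(drops <= allowed)

    def test_determinism_bitwise(self):
        pop, profiles, init, fix = _noiseless_cohort_and_init()
        opts = pv.FitOptions(n_samples=60, max_iter=4, seed=11, fix=fix, rk4_step=0.02)
        results = []
        for _ in range(2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results.append(pv.fit_popk(profiles, init, opts))
        assert results[0].objective == results[1].objective
        assert results[0].estimates.theta == results[1].estimates.theta
        assert results[0].estimates.omega2 == results[1].estimates.omega2

    def test_all_blq_subject_excluded_with_warning(self, population):
        profiles, _ = pv.generate_cohort(population, seed=4)
        blq = pv.PlasmaProfile(
            "ghost", "IR", 20.0, np.array([1.0, 2.0, 3.0]), np.zeros(3),
            np.ones(3, dtype=bool),
        )
        fix = frozenset({"imax", "hill_stomach", "hill_intestine"})
        init = replace(
            population,
            theta=dict(population.theta),
            omega2={k: v for k, v in population.omega2.items() if k not in fix},
            sigma=0.2,
        )
        opts = pv.FitOptions(n_samples=40, max_iter=2, seed=1, fix=fix, rk4_step=0.02)
        with pytest.warns(UserWarning, match="ghost"):
            res = pv.fit_popk(profiles + [blq], init, opts)
        assert res.diagnostics["n_subjects"] == len(profiles)


class TestVisualPredictiveCheck:
    def test_degenerate_bands_coincide_with_typical(self, population, rk4_config):
        pop0 = replace(population, omega2={}, sigma=1e-9)
        design = pv.StudyDesign(formulations=(("IR", 20.0),))
        vpc = pv.visual_predictive_check(pop0, design, n_sim=100, seed=1)
        typical = pv.simulate_pk(
            defaults.typical_subject("IR"), design.plasma_times, config=rk4_config
        )
        np.testing.assert_allclose(vpc.p50, typical.concentrations, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(vpc.p5, vpc.p95, rtol=1e-5, atol=1e-6)

    def test_median_band_starts_at_zero(self, population):
        design = pv.StudyDesign(formulations=(("IR", 20.0),))
        vpc = pv.visual_predictive_check(population, design, n_sim=100, seed=2)
        assert vpc[vpc.time_h == 0.0].p50.iloc[0] == 0.0

    def test_bands_widen_with_variability(self, population):
        design = pv.StudyDesign(formulations=(("SR_fast", 60.0),))
        narrow = replace(population, omega2={"cl": 0.05}, sigma=1e-9)
        wide = replace(population, omega2={"cl": 0.5}, sigma=1e-9)
        v_n = pv.visual_predictive_check(narrow, design, n_sim=150, seed=3)
        v_w = pv.visual_predictive_check(wide, design, n_sim=150, seed=3)
        t = 4.0
        width = lambda v: float(
            v[v.time_h == t].p95.iloc[0] - v[v.time_h == t].p5.iloc[0]
        )
        assert width(v_w) > width(v_n)

    def test_small_simulation_count_rejected(self, population):
        with pytest.raises(ValueError):
            pv.visual_predictive_check(population, pv.StudyDesign(), n_sim=10, seed=0)
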