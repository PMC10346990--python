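"""Parameter estimation: guesses, recovery, diagnostics, degeneracy."""

import warnings

import numpy as np
import pytest

from ssisfit import (
    BindingParameters,
    FitDiagnosticWarning,
    InjectionHeats,
    NoiseSpec,
    fit_report,
    fit_ssis,
    initial_guess,
    simulate_heats,
)


def _quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FitDiagnosticWarning)
        return fit_ssis(*args, **kwargs)


class TestInitialGuess:
    def test_round_trip_guesses_near_truth(self, mg_params, mg_schedule, noiseless_heats):
        g = initial_guess(noiseless_heats, mg_schedule)
        # site-count and enthalpy heuristics land within a factor of 3
        assert mg_params.n_sites / 3 < g.n_sites < mg_params.n_sites * 3
        assert mg_params.enthalpy / 3 < g.enthalpy < mg_params.enthalpy * 3
        assert g.binding_constant == 1e3  # fixed conventional start

    def test_all_zero_heats_rejected(self, mg_schedule):
        with pytest.raises(ValueError, match="zero"):
            initial_guess(InjectionHeats(heat=np.zeros(35)), mg_schedule)

    def test_no_half_height_crossing_uses_final_ratio(self, mg_schedule):
        # nearly flat isotherm, far from saturation
        heats = InjectionHeats(heat=np.linspace(1.0e-4, 0.95e-4, 35))
        with pytest.warns(FitDiagnosticWarning, match="half"):
            g = initial_guess(heats, mg_schedule)
        assert g.n_sites == pytest.approx(33.9, abs=0.1)

    def test_too_few_points_rejected(self, mg_schedule):
        short = InjectionHeats(heat=np.ones(4))
        with pytest.raises(ValueError, match="at least 5"):
            initial_guess(short, mg_schedule)


class TestFitRecovery:
    @pytest.mark.parametrize("name", ["ca-16.5", "mg-16.5", "mg-21.5-0.8", "mg-21.5-1.7", "mg-21.5-2.5"])
    def test_noiseless_recovery_all_designs(self, name):
        from ssisfit import get_design

        d = get_design(name)
        sch = d.schedule()
        res = _quiet_fit(simulate_heats(d.params, sch), sch)
        assert res.converged
        assert res.params.n_sites == pytest.approx(d.params.n_sites, rel=1e-6)
        assert res.params.binding_constant == pytest.approx(d.params.binding_constant, rel=1e-6)
        assert res.params.enthalpy == pytest.approx(d.params.enthalpy, rel=1e-6)

    def test_ssr_not_worse_than_initial_guess(self, mg_params, mg_schedule):
        from ssisfit.titration import predicted_heats

        noisy = simulate_heats(
            mg_params, mg_schedule,
            NoiseSpec(heat_sigma=0.02, heat_sigma_mode="fraction_of_max", seed=11),
        )
        g = initial_guess(noisy, mg_schedule)
        ssr0 = float(np.sum((noisy.heat - predicted_heats(g, mg_schedule)) ** 2))
        res = _quiet_fit(noisy, mg_schedule, init=g)
        assert res.ssr <= ssr0

    def test_shuffled_heats_never_raise(self, mg_params, mg_schedule):
        rng = np.random.default_rng(3)
        shuffled = mg_schedule and simulate_heats(mg_params, mg_schedule).heat.copy()
        rng.shuffle(shuffled)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = fit_ssis(InjectionHeats(heat=shuffled), mg_schedule)
        assert isinstance(res.converged, bool)
        assert res.warnings or not res.converged or res.low_confidence

    def test_discard_first_uses_one_fewer_point(self, mg_params, mg_schedule, noiseless_heats):
        res = _quiet_fit(noiseless_heats, mg_schedule, discard_first=True)
        assert res.n_points_used == 34
        assert res.params.n_sites == pytest.approx(mg_params.n_sites, rel=1e-6)

    def test_macroion_override_changes_c_value(self, mg_params, mg_schedule, noiseless_heats):
        res = _quiet_fit(noiseless_heats, mg_schedule)
        assert res.c_value == pytest.approx(
            res.params.binding_constant * res.params.n_sites * 0.032e-3, rel=1e-12
        )


class TestDiagnostics:
    def test_scaled_down_heats_flag_low_confidence(self, mg_params, mg_schedule):
        # a 10x weaker signal at unchanged absolute noise: the ionic-strength
        # failure mode -- fit must warn, not crash
        truth = simulate_heats(mg_params, mg_schedule).heat
        sigma = 0.02 * np.abs(truth).max()
        rng = np.random.default_rng(7)
        weak = 0.1 * truth + rng.normal(0.0, sigma, truth.size)
        with pytest.warns(FitDiagnosticWarning):
            res = fit_ssis(InjectionHeats(heat=weak), mg_schedule)
        assert res.low_confidence
        rel_se = res.standard_errors["binding_constant"] / res.params.binding_constant
        assert not np.isfinite(rel_se) or rel_se > 0.5

    def test_report_refuses_unconverged(self, mg_params):
        res_like = _quiet_fit(
            simulate_heats(mg_params, mg_schedule_default()), mg_schedule_default()
        )
        res_like.converged = False
        with pytest.raises(ValueError, match="converge"):
            fit_report(res_like)


def mg_schedule_default():
    from ssisfit import get_design

    return get_design("mg-16.5").schedule()


class TestFitReport:
    @pytest.mark.parametrize("kb,dg", [(6.3e3, -22.0), (6.5e3, -22.1), (5.1e3, -21.5)])
    def test_report_gibbs_values(self, mg_schedule, noiseless_heats, kb, dg):
        res = _quiet_fit(noiseless_heats, mg_schedule)
        res.params = BindingParameters(res.params.n_sites, kb, res.params.enthalpy)
        rep = fit_report(res, 303.15)
        assert round(rep["dG_kJ_mol"], 1) == dg
        assert rep["Kb_1e3_M"] == pytest.approx(kb / 1e3)

    def test_gibbs_uncertainty_propagation(self, mg_schedule, noiseless_heats):
        res = _quiet_fit(noiseless_heats, mg_schedule)
        res.standard_errors["binding_constant"] = 0.5e3
        rep = fit_report(res, 303.15)
        expected = 8.314 * 303.15 * 0.5e3 / res.params.binding_constant / 1e3
        assert rep["dG_err_kJ_mol"] == pytest.approx(expected, rel=1e-12)

    def test_log_and_linear_parameterizations_agree(self, mg_params, mg_schedule):
        # optimizing ln Kb (package) and Kb directly (independent scipy
        # route) must find the same optimum on a well-conditioned problem
        from scipy.optimize import least_squares

        from ssisfit.titration import predicted_heats

        noisy = simulate_heats(
            mg_params, mg_schedule,
            NoiseSpec(heat_sigma=0.01, heat_sigma_mode="fraction_of_max", seed=5),
        )
        a = _quiet_fit(noisy, mg_schedule)

        def resid(x):
            return noisy.heat - predicted_heats(
                BindingParameters(x[0], x[1], x[2]), mg_schedule
            )

        linear = least_squares(
            resid, x0=[5.0, 1e3, 5.0], bounds=([1e-6, 1e-6, -np.inf], np.inf),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        assert a.params.n_sites == pytest.approx(linear.x[0], rel=1e-4)
        assert a.params.binding_constant == pytest.approx(linear.x[1], rel=1e-4)
        assert a.params.enthalpy == pytest.approx(linear.x[2], rel=1e-4)
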