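"""Parametric survival likelihoods, MLE, AIC selection, PH adjustment."""
import numpy as np
import pytest

from hccea import (PseudoIPD, TrialArmSpec, apply_hr, fit_all,
                   fit_mle, loglik, select_by_aic, simulate_arm, survival_at)
from hccea.survival import SurvivalFit, log_hazard, log_sf, sf


class TestLoglik:
    def test_exponential_closed_form(self):
        ipd = PseudoIPD([1, 2, 3], [1, 1, 1])
        lam = 0.5
        assert loglik("exponential", {"rate": lam}, ipd) == \
            pytest.approx(3 * np.log(lam) - 6 * lam)

    def test_all_censored_is_n_log_s(self):
        T, n = 7.0, 5
        ipd = PseudoIPD([T] * n, [0] * n)
        for fam, params in [("exponential", {"rate": 0.2}),
                            ("weibull", {"scale": 5, "shape": 1.4}),
                            ("loglogistic", {"scale": 5, "shape": 1.4}),
                            ("lognormal", {"mu": 1.5, "sigma": 0.7}),
                            ("gompertz", {"rate": 0.1, "shape": 0.05})]:
            expected = n * log_sf(fam, params, T)
            assert loglik(fam, params, ipd) == pytest.approx(float(expected))

    def test_weibull_shape_one_nests_exponential(self):
        ipd = PseudoIPD([0.5, 1.2, 3.3, 4.0], [1, 0, 1, 1])
        assert loglik("weibull", {"scale": 2.0, "shape": 1.0}, ipd) == \
            pytest.approx(loglik("exponential", {"rate": 0.5}, ipd))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            PseudoIPD([0.0, 1.0], [1, 1])
        with pytest.raises(ValueError, match="positive"):
            log_hazard("weibull", {"scale": 1, "shape": 2}, 0.0)


class TestFitMLE:
    def test_exponential_rate_is_events_over_total_time(self):
        ipd = PseudoIPD([1, 2, 3], [1, 1, 1])
        fit = fit_mle("exponential", ipd)
        assert fit.params["rate"] == pytest.approx(0.5, rel=1e-6)

    def test_exponential_numerical_matches_closed_form_with_censoring(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(8.0, 400)
        times = np.minimum(t, 12.0)
        events = (t <= 12.0).astype(int)
        ipd = PseudoIPD(times, events)
        closed = events.sum() / times.sum()
        fit = fit_mle("exponential", ipd)
        assert fit.params["rate"] == pytest.approx(closed, rel=1e-6)

    def test_loglogistic_parameter_recovery(self):
        spec = TrialArmSpec("a", "loglogistic", {"scale": 10.0, "shape": 2.0},
                            5000, max_followup=np.inf, seed=2)
        fit = fit_mle("loglogistic", simulate_arm(spec))
        assert fit.params["scale"] == pytest.approx(10.0, rel=0.05)
        assert fit.params["shape"] == pytest.approx(2.0, rel=0.05)

    def test_gompertz_beats_exponential_on_gompertz_data(self):
        spec = TrialArmSpec("a", "gompertz", {"rate": 0.03, "shape": 0.15},
                            2000, max_followup=np.inf, seed=3)
        ipd = simulate_arm(spec)
        f_gom = fit_mle("gompertz", ipd)
        f_exp = fit_mle("exponential", ipd)
        assert f_gom.loglik >= f_exp.loglik - 1e-6

    def test_local_optimality(self):
        spec = TrialArmSpec("a", "weibull", {"scale": 7.0, "shape": 1.6},
                            800, max_followup=20.0, seed=4)
        ipd = simulate_arm(spec)
        fit = fit_mle("weibull", ipd)
        for eps in (1e-3, -1e-3):
            for pert in ({"scale": fit.params["scale"] * (1 + eps),
                          "shape": fit.params["shape"]},
                         {"scale": fit.params["scale"],
                          "shape": fit.params["shape"] * (1 + eps)}):
                assert loglik("weibull", pert, ipd) <= fit.loglik + 1e-9

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            fit_mle("weibull", PseudoIPD([1.0, 2.0], [0, 0]))

    def test_cross_check_against_lifelines(self):
        # independent implementation oracle: lifelines' log-logistic fitter
        # uses the same S(t) = 1/(1+(t/alpha)^beta) parameterization
        from lifelines import LogLogisticFitter

        spec = TrialArmSpec("a", "loglogistic", {"scale": 8.0, "shape": 1.7},
                            1000, max_followup=30.0, seed=6)
        ipd = simulate_arm(spec)
        ours = fit_mle("loglogistic", ipd)
        llf = LogLogisticFitter().fit(ipd.times, ipd.events)
        assert ours.params["scale"] == pytest.approx(llf.alpha_, rel=1e-3)
        assert ours.params["shape"] == pytest.approx(llf.beta_, rel=1e-3)
        assert ours.loglik == pytest.approx(
            llf.log_likelihood_, rel=1e-6)


class TestAICSelection:
    def test_minimum_aic_wins(self):
        fits = [SurvivalFit("exponential", {"rate": 1}, -49.0, 1),
                SurvivalFit("weibull", {"scale": 1, "shape": 1}, -47.0, 2),
                SurvivalFit("gompertz", {"rate": 1, "shape": 1}, -49.5, 2)]
        assert select_by_aic(fits).family == "weibull"

    def test_tie_goes_to_fewer_parameters_then_family_order(self):
        f1 = SurvivalFit("loglogistic", {"scale": 1, "shape": 1}, -49.0, 2)
        f2 = SurvivalFit("exponential", {"rate": 1}, -50.0, 1)  # same AIC 102
        assert select_by_aic([f1, f2]).family == "exponential"
        f3 = SurvivalFit("lognormal", {"mu": 0, "sigma": 1}, -49.0, 2)
        assert select_by_aic([f1, f3]).family == "loglogistic"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_by_aic([])

    def test_aic_identity_on_fitted_models(self):
        spec = TrialArmSpec("a", "lognormal", {"mu": 2.0, "sigma": 0.8},
                            300, max_followup=40.0, seed=8)
        for f in fit_all(simulate_arm(spec)):
            assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik)


class TestHazardRatioAdjustment:
    def test_hr_one_is_identity(self):
        base = SurvivalFit("weibull", {"scale": 5.0, "shape": 1.2}, -1.0, 2)
        adj = apply_hr(base, 1.0)
        t = np.linspace(0, 20, 50)
        assert np.allclose(adj.sf(t), base.sf(t))

    def test_squares_survival_at_hr_two(self):
        base = SurvivalFit("loglogistic", {"scale": 4.0, "shape": 2.0},
                           -1.0, 2)
        adj = apply_hr(base, 2.0)
        assert adj.sf(4.0) == pytest.approx(0.25)  # S_base(scale) = 0.5

    def test_exponential_family_closed_under_ph(self):
        base = SurvivalFit("exponential", {"rate": 0.3}, -1.0, 1)
        adj = apply_hr(base, 0.5)
        t = np.linspace(0, 30, 40)
        assert np.allclose(adj.sf(t), np.exp(-0.15 * t))

    def test_hazard_scales_by_hr_numerically(self):
        base = SurvivalFit("gompertz", {"rate": 0.05, "shape": 0.08},
                           -1.0, 2)
        hr = 0.7
        adj = apply_hr(base, hr)
        t = np.linspace(0.5, 24, 30)
        dt = 1e-5
        h_base = -(np.log(base.sf(t + dt)) - np.log(base.sf(t - dt))) / (2 * dt)
        h_adj = -(np.log(adj.sf(t + dt)) - np.log(adj.sf(t - dt))) / (2 * dt)
        assert np.allclose(h_adj, hr * h_base, rtol=1e-4)

    def test_nonpositive_hr_rejected(self):
        base = SurvivalFit("exponential", {"rate": 0.3}, -1.0, 1)
        with pytest.raises(ValueError):
            apply_hr(base, 0.0)


class TestSurvivalAt:
    def test_known_values(self):
        ll = SurvivalFit("loglogistic", {"scale": 6.0, "shape": 1.5}, -1, 2)
        assert survival_at(ll, 6.0) == pytest.approx(0.5)
        assert survival_at(ll, 0.0) == 1.0
        ex = SurvivalFit("exponential", {"rate": 0.1}, -1, 1)
        assert survival_at(ex, 10.0) == pytest.approx(np.exp(-1.0))

    def test_monotone_and_bounded(self):
        for fam, params in [("weibull", {"scale": 5, "shape": 0.8}),
                            ("gompertz", {"rate": 0.02, "shape": 0.2})]:
            fit = SurvivalFit(fam, params, -1, 2)
            t = np.linspace(0, 50, 200)
            s = survival_at(fit, t)
            assert np.all((s >= 0) & (s <= 1))
            assert np.all(np.diff(s) <= 1e-12)

    def test_negative_time_rejected(self):
        fit = SurvivalFit("exponential", {"rate": 0.1}, -1, 1)
        with pytest.raises(ValueError):
            survival_at(fit, -1.0)


@pytest.mark.parametrize("family,params", [
    ("exponential", {"rate": 0.12}),
    ("weibull", {"scale": 9.0, "shape": 1.4}),
    ("loglogistic", {"scale": 7.0, "shape": 1.8}),
    ("lognormal", {"mu": 2.1, "sigma": 0.6}),
    ("gompertz", {"rate": 0.04, "shape": 0.12}),
])
def test_parameter_recovery_low_bias(family, params):
    """Mean estimate over 6 seeds at n=2000 within 5% of truth per family."""
    ests = {k: [] for k in params}
    for seed in range(6):
        spec = TrialArmSpec("a", family, params, 2000,
                            max_followup=np.inf, seed=seed)
        fit = fit_mle(family, simulate_arm(spec))
        for k in params:
            ests[k].append(fit.params[k])
    for k, truth in params.items():
        assert np.mean(ests[k]) == pytest.approx(truth, rel=0.05)
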