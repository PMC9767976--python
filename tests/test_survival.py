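"""Parametric families, censored likelihood, model selection and reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import (ExponentialFitter, KaplanMeierFitter, LogLogisticFitter,
                       LogNormalFitter, WeibullFitter)

from psmcea import (DigitizedCurve, ModelFit, ParametricSurvival, PseudoIPD,
                    fit_mle, log_likelihood, reconstruct_ipd, select_best,
                    survival_prob)

from conftest import fd_hessian

EXAMPLE_MODELS = [
    ParametricSurvival("exponential", 0.1),
    ParametricSurvival("weibull", 1.5, 10.0),
    ParametricSurvival("gompertz", 0.08, 0.05),
    ParametricSurvival("gompertz", -0.03, 0.08),
    ParametricSurvival("lognormal", 2.1923, 0.8939621),
    ParametricSurvival("loglogistic", 2.828918, 0.5166103),
    ParametricSurvival("gengamma", 2.0, 0.9, 0.7),
    ParametricSurvival("gengamma", 2.0, 0.9, -1.2),
]


class TestSurvivalProb:
    def test_log_location_scale_median(self):
        # at t = e^mu a log-location-scale family sits at its median
        m = ParametricSurvival("loglogistic", 2.828918, 0.5166103)
        assert survival_prob(m, np.exp(2.828918)) == pytest.approx(0.5, abs=1e-12)

    def test_starts_at_one(self):
        for m in EXAMPLE_MODELS:
            assert survival_prob(m, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_lognormal_tail_matches_density_quadrature(self):
        # frozen value of the integral of the lognormal density over [18, inf)
        m = ParametricSurvival("lognormal", 2.1923, 0.8939621)
        assert survival_prob(m, 18.0) == pytest.approx(0.21743830365989894, abs=1e-9)

    def test_gengamma_small_q_converges_to_lognormal(self):
        ln = ParametricSurvival("lognormal", 2.0, 0.9)
        t = np.linspace(0.1, 60, 40)
        for q in (1e-7, -1e-7, 0.01, -0.01):
            # the gap shrinks linearly in |Q|
            gg = ParametricSurvival("gengamma", 2.0, 0.9, q)
            assert np.allclose(gg.survival(t), ln.survival(t), atol=0.2 * abs(q) + 1e-9)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            ParametricSurvival("weibull", 1.5, -1.0)
        with pytest.raises(ValueError):
            ParametricSurvival("gengamma", 1.0, 1.0)  # missing Q
        with pytest.raises(ValueError):
            survival_prob(EXAMPLE_MODELS[0], -1.0)

    @pytest.mark.parametrize("model", EXAMPLE_MODELS,
                             ids=lambda m: f"{m.family}-{m.location:g}")
    def test_one_minus_survival_is_a_cdf(self, model):
        t = np.linspace(0.0, 1e4, 2001)
        s = model.survival(t)
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-12)
        assert 1.0 - s[-1] <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(mu=st.floats(-1, 4), sigma=st.floats(0.2, 2.0),
           family=st.sampled_from(["lognormal", "loglogistic"]))
    def test_log_location_scale_monotone(self, mu, sigma, family):
        m = ParametricSurvival(family, mu, sigma)
        t = np.linspace(0, 500, 300)
        s = m.survival(t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert m.survival(np.exp(mu)) == pytest.approx(0.5, abs=1e-10)


class TestLogLikelihood:
    def test_single_event_exponential(self):
        m = ParametricSurvival("exponential", 1.0)
        data = PseudoIPD(np.array([1.0]), np.array([1]))
        assert log_likelihood(m, data) == pytest.approx(-1.0, abs=1e-12)

    def test_single_censored_exponential(self):
        m = ParametricSurvival("exponential", 0.5)
        data = PseudoIPD(np.array([2.0]), np.array([0]))
        assert log_likelihood(m, data) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_per_observation_closed_form(self):
        # Weibull terms: ln f = ln(a/b) + (a-1) ln(t/b) - (t/b)^a ; ln S = -(t/b)^a
        a, b = 1.5, 10.0
        rng = np.random.default_rng(42)
        t = b * rng.weibull(a, size=50)
        e = (rng.uniform(size=50) < 0.8).astype(int)
        m = ParametricSurvival("weibull", a, b)
        z = (t / b) ** a
        expected = np.where(e == 1, np.log(a / b) + (a - 1) * np.log(t / b) - z, -z).sum()
        assert log_likelihood(m, PseudoIPD(t, e)) == pytest.approx(expected, abs=1e-10)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            PseudoIPD(np.array([]), np.array([]))


class TestFitMLE:
    def test_exponential_closed_form_complete(self):
        data = PseudoIPD(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        with pytest.warns(UserWarning):  # tiny sample
            fit = fit_mle("exponential", data)
        assert fit.model.location == pytest.approx(0.5, abs=1e-15)

    def test_exponential_closed_form_censored(self):
        # events / total time at risk = 2 / 4
        data = PseudoIPD(np.array([1.0, 1.0, 2.0]), np.array([1, 1, 0]))
        with pytest.warns(UserWarning):
            fit = fit_mle("exponential", data)
        assert fit.model.location == pytest.approx(0.5, abs=1e-15)

    def test_all_censored_rejected(self):
        data = PseudoIPD(np.ones(20), np.zeros(20, dtype=int))
        with pytest.raises(ValueError):
            fit_mle("exponential", data)

    def test_information_criteria_identities(self):
        rng = np.random.default_rng(3)
        data = PseudoIPD(rng.exponential(10, 100), np.ones(100, dtype=int))
        fit = fit_mle("weibull", data)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        assert fit.bic == pytest.approx(fit.n_params * np.log(fit.n_obs) - 2 * fit.loglik)

    @pytest.mark.parametrize("family,lifelines_cls,extract", [
        ("weibull", WeibullFitter, lambda f: (f.rho_, f.lambda_)),
        ("lognormal", LogNormalFitter, lambda f: (f.mu_, f.sigma_)),
        ("loglogistic", LogLogisticFitter, lambda f: (np.log(f.alpha_), 1.0 / f.beta_)),
    ])
    def test_agrees_with_lifelines(self, family, lifelines_cls, extract):
        """Independent-route check: our MLE vs the lifelines fitters."""
        truth = ParametricSurvival(family, *{
            "weibull": (1.4, 12.0), "lognormal": (2.2, 0.9), "loglogistic": (2.4, 0.6),
        }[family])
        rng = np.random.default_rng(7)
        t = truth.rvs(800, rng)
        cens = rng.exponential(40, 800)
        obs = np.minimum(t, cens)
        e = (t <= cens).astype(int)
        ours = fit_mle(family, PseudoIPD(obs, e)).model
        ll = lifelines_cls().fit(obs, e)
        theirs = extract(ll)
        ours_params = ((ours.location, ours.scale) if family != "weibull"
                       else (ours.location, ours.scale))
        if family == "weibull":
            theirs = (theirs[0], theirs[1])  # (shape, scale)
        assert np.allclose(ours_params, theirs, rtol=1e-3)

    def test_recovers_lognormal_truth_within_3_se(self):
        truth = ParametricSurvival("lognormal", 2.19, 0.89)
        rng = np.random.default_rng(11)
        t = truth.rvs(1000, rng)
        cens = rng.exponential(45, 1000)  # about 20 % censoring
        obs, e = np.minimum(t, cens), (t <= cens).astype(int)
        data = PseudoIPD(obs, e)
        fit = fit_mle("lognormal", data)

        def negll(x):
            return -log_likelihood(ParametricSurvival("lognormal", x[0], x[1]), data)

        H = fd_hessian(negll, [fit.model.location, fit.model.scale])
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        assert abs(fit.model.location - 2.19) < 3 * se[0]
        assert abs(fit.model.scale - 0.89) < 3 * se[1]


class TestSelectBest:
    @staticmethod
    def _fit(family, aic, n_params, n_obs=327):
        if family == "exponential":
            model = ParametricSurvival("exponential", 0.1)
        elif family == "gengamma":
            model = ParametricSurvival("gengamma", 2.0, 1.0, 0.5)
        else:
            model = ParametricSurvival(family, 1.0, 1.0)
        return ModelFit(model, loglik=(2 * n_params - aic) / 2.0,
                        n_params=n_params, n_obs=n_obs)

    def test_published_criteria_pick_loglogistic(self):
        # AIC values of the six candidates for one arm's overall survival
        fits = [self._fit("exponential", 649.7547, 1),
                self._fit("weibull", 615.6429, 2),
                self._fit("gompertz", 631.4136, 2),
                self._fit("lognormal", 613.2866, 2),
                self._fit("loglogistic", 610.3871, 2),
                self._fit("gengamma", 613.2811, 3)]
        assert select_best(fits, "aic").model.family == "loglogistic"
        assert select_best(fits, "bic").model.family == "loglogistic"

    def test_tie_broken_by_family_order(self):
        a = self._fit("lognormal", 500.0, 2)
        b = self._fit("loglogistic", 500.0, 2)
        assert select_best([b, a], "aic").model.family == "lognormal"

    def test_fewer_parameters_win_ties(self):
        # equal AIC, different complexity
        a = self._fit("gengamma", 500.0, 3)
        b = self._fit("loglogistic", 500.0, 2)
        assert select_best([a, b], "aic") is b

    def test_single_fit_warns(self):
        only = self._fit("weibull", 100.0, 2)
        with pytest.warns(UserWarning):
            assert select_best([only]) is only

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError):
            select_best([self._fit("weibull", 1.0, 2, 100),
                         self._fit("lognormal", 1.0, 2, 200)])


class TestReconstructIPD:
    def test_exact_step_allocation(self):
        curve = DigitizedCurve([1.0, 2.0], [0.9, 0.8])
        ipd = reconstruct_ipd(curve, 10)
        assert ipd.n == 10
        assert list(ipd.times[ipd.events == 1]) == [1.0, 2.0]
        assert (ipd.events == 0).sum() == 8
        assert np.all(ipd.times[ipd.events == 0] == 2.0)

    def test_flat_curve_all_censored(self):
        curve = DigitizedCurve([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        ipd = reconstruct_ipd(curve, 25)
        assert ipd.n_events == 0 and ipd.n == 25

    def test_km_of_reconstruction_matches_curve(self):
        m = ParametricSurvival("weibull", 1.3, 14.0)
        times = np.linspace(1, 30, 25)
        curve = DigitizedCurve(times, m.survival(times))
        n_start = 200
        ipd = reconstruct_ipd(curve, n_start)
        km = KaplanMeierFitter().fit(ipd.times, ipd.events)
        est = km.survival_function_at_times(times).to_numpy()
        assert np.all(np.abs(est - curve.survival) <= 1.0 / (2 * n_start) + 1e-9)

    def test_roundtrip_recovers_exponential_rate(self):
        lam = 0.1
        times = np.linspace(1, 30, 30)
        curve = DigitizedCurve(times, np.exp(-lam * times))
        ipd = reconstruct_ipd(curve, 300)
        fit = fit_mle("exponential", ipd)
        assert fit.model.location == pytest.approx(lam, rel=0.10)

    def test_risk_table_constrains_censoring(self):
        # half the cohort is lost between the two points; events must respect it
        curve = DigitizedCurve([1.0, 2.0, 3.0], [0.9, 0.8, 0.7],
                               n_risk=[90.0, 40.0, 30.0])
        ipd = reconstruct_ipd(curve, 100)
        assert ipd.n == 100
        at_risk_late = ((ipd.times >= 2.0).sum())
        assert abs(at_risk_late - 40) <= 2

    def test_repair_rejects_gross_violations(self):
        curve = DigitizedCurve([1.0, 2.0], [0.5, 0.6])
        with pytest.raises(ValueError):
            curve.repaired()

    def test_repair_smooths_small_wiggles(self):
        curve = DigitizedCurve([1.0, 2.0, 3.0], [0.80, 0.81, 0.70])
        fixed = curve.repaired()
        assert np.all(np.diff(fixed.survival) <= 0)
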