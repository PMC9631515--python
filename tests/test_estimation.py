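"""Bayesian estimation: basal glucose, posterior kernel, fits and chaining."""

import math

import numpy as np
import pytest
from scipy import stats

import glucomod as gm
from glucomod.estimation import ParameterMap
from glucomod.priors import lognormal_cv_from_sigma, lognormal_sigma_from_cv


def _day_data(meal1_samples):
    """Build a minimal first-meal response including the fasting sample."""
    times, glucose = zip(*meal1_samples)
    spec = gm.MealSpec(t_meal=0.0, cho_dose=1.1)
    return gm.MealResponseData(times=np.array(times), glucose=np.array(glucose),
                               meal=spec, meal_index=1)


def _schedule_response(values=None, glucose_const=None, seed=0):
    times = np.array(gm.MEAL_SCHEDULE_MIN)
    if values is None:
        values = np.full(times.size, glucose_const)
    return gm.MealResponseData(times=times, glucose=np.asarray(values),
                               meal=gm.MealSpec(t_meal=0.0, cho_dose=1.1))


class TestComputeGb:
    def test_mean_of_the_four_named_samples(self):
        data = _day_data([(-15, 92.0), (0, 90.0), (2, 89.0), (5, 89.0),
                          (240, 91.0)])
        assert gm.compute_gb(data) == pytest.approx(90.0)

    def test_constant_samples(self):
        data = _day_data([(-15, 87.0), (0, 87.0), (2, 87.0), (5, 87.0), (240, 87.0)])
        assert gm.compute_gb(data) == pytest.approx(87.0)

    def test_missing_sample_is_an_error(self):
        data = _day_data([(0, 90.0), (2, 89.0), (5, 89.0), (240, 91.0)])
        with pytest.raises(gm.DataError, match="-15"):
            gm.compute_gb(data)


class TestTransforms:
    def test_lognormal_median_cv_round_trip(self):
        for cv in (0.1, 0.5, 1.0):
            assert lognormal_cv_from_sigma(lognormal_sigma_from_cv(cv)) == pytest.approx(cv)

    def test_logit_prior_matches_requested_cv(self):
        p = gm.ParamPrior(0.5, 0.5, transform="logit")
        assert p.cv_from_sigma(p.sigma) == pytest.approx(0.5, rel=1e-6)
        assert p.to_natural(p.mu) == pytest.approx(0.5)

    def test_reported_cv_round_trips_with_log_scale_sd(self):
        p = gm.ParamPrior(0.02, 0.5)
        sigma = p.sigma
        # log-normal identity: CV = sqrt(exp(sigma^2) - 1)
        assert p.cv_from_sigma(sigma) == pytest.approx(math.sqrt(math.expm1(sigma**2)))


class TestLogJoint:
    def test_matches_brute_force_reimplementation(self, synthetic_day):
        data = synthetic_day.meals[0]
        priors = gm.default_gom_priors()
        obs = gm.ObservationModel.from_cv(data.fit_glucose, cv=0.02)
        pmap = ParameterMap.for_gom(priors, gb=90.0, g0=float(data.fit_glucose[0]),
                                    x0=0.0, A=data.meal.A)
        theta = pmap.prior_mu + 0.1
        got = gm.log_joint(theta, data, pmap, obs)

        sim = gm.simulate("gom", pmap.build_params(theta), data.fit_times)
        expected = float(np.sum(stats.norm.logpdf(data.fit_glucose, sim.glucose, obs.sd)))
        expected += float(np.sum(stats.norm.logpdf(theta, pmap.prior_mu, pmap.prior_sigma)))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_perfect_fit_likelihood_is_the_normalisation(self, synthetic_day):
        data = synthetic_day.meals[0]
        priors = gm.default_gom_priors()
        obs = gm.ObservationModel.from_cv(data.fit_glucose, cv=0.02)
        pmap = ParameterMap.for_gom(priors, gb=90.0, g0=float(data.fit_glucose[0]),
                                    x0=0.0, A=data.meal.A)
        theta = pmap.prior_mu
        sim = gm.simulate("gom", pmap.build_params(theta), data.fit_times)
        # overwrite the data with the simulation: zero residuals
        perfect = gm.MealResponseData(times=data.times,
                                      glucose=np.concatenate(([data.glucose[0]], sim.glucose))
                                      if -15.0 in data.times else sim.glucose,
                                      meal=data.meal, meal_index=1)
        got = gm.log_joint(theta, perfect, pmap, obs)
        loglik_expected = -float(np.sum(np.log(obs.sd * math.sqrt(2 * math.pi))))
        prior_at_mode = float(np.sum(stats.norm.logpdf(theta, pmap.prior_mu, pmap.prior_sigma)))
        assert got == pytest.approx(loglik_expected + prior_at_mode, abs=1e-9)

    def test_infeasible_proposal_is_rejected(self, synthetic_day):
        data = synthetic_day.meals[0]
        priors = gm.default_omm_priors(data.meal.A)
        pmap = ParameterMap.for_omm(priors, gb=90.0, ib=8.0,
                                    g0=float(data.fit_glucose[0]), x0=0.0,
                                    A=data.meal.A)
        obs = gm.ObservationModel.from_cv(data.fit_glucose, cv=0.02)
        theta = pmap.prior_mu.copy()
        theta[3:] += 10.0  # heights so large the AUC constraint must fail
        ins = gm.InsulinInterpolant(data.times, data.insulin)
        assert gm.log_joint(theta, data, pmap, obs, insulin=ins) == -np.inf


class TestFitMeal:
    def test_prior_recovery_without_likelihood(self):
        """With the likelihood disabled the posterior must be the prior."""
        data = _schedule_response(glucose_const=90.0)
        fit = gm.fit_meal(data, model="gom", include_likelihood=False, seed=1)
        priors = gm.default_gom_priors()
        for name, prior in priors.items():
            assert fit.medians[name] == pytest.approx(prior.median, rel=1e-2)
            assert fit.cvs[name] == pytest.approx(prior.cv, rel=1e-2)

    def test_noise_free_self_consistency(self, synthetic_day):
        """Noise-free data + priors centred at truth -> estimates at truth."""
        truth = synthetic_day.subject.true_gom
        noise_free = gm.make_day(synthetic_day.subject, noise_cv=0.0, seed=0)
        data = noise_free.meals[0]
        priors = _priors_at_truth(truth)
        fit = gm.fit_meal(data, priors=priors, model="gom", seed=0, gb=truth.gb)
        true_nat = _true_natural(truth)
        for name, tv in true_nat.items():
            assert fit.medians[name] == pytest.approx(tv, rel=1e-2), name

    def test_uninformative_trace_pins_ga_timing_to_prior(self):
        # a constant trace after a negligible meal carries no information
        # about GA timing, so T1/T2 posteriors must sit at their priors
        # (with a substantial dose the flat trace IS informative: the fit
        # pushes the GA mass beyond the 240-min window)
        times = np.array(gm.MEAL_SCHEDULE_MIN)
        data = gm.MealResponseData(times=times, glucose=np.full(times.size, 90.0),
                                   meal=gm.MealSpec(t_meal=0.0, cho_dose=1e-3))
        fit = gm.fit_meal(data, model="gom", seed=0)
        priors = gm.default_gom_priors()
        for name in ("T1", "T2"):
            assert fit.medians[name] == pytest.approx(priors[name].median, rel=0.05)
            assert fit.cvs[name] == pytest.approx(priors[name].cv, rel=0.10)

    def test_widening_beta_prior_inflates_sg_uncertainty(self, synthetic_day):
        data = synthetic_day.meals[0]
        narrow = gm.fit_meal(data, model="gom", seed=0)
        wide_priors = gm.default_gom_priors()
        wide_priors["beta"] = gm.ParamPrior(30.0, 0.50)
        wide = gm.fit_meal(data, priors=wide_priors, model="gom", seed=0)
        assert wide.cvs["sg"] > narrow.cvs["sg"]

    def test_omm_requires_insulin(self):
        data = _schedule_response(glucose_const=95.0)
        with pytest.raises(gm.DataError, match="insulin"):
            gm.fit_meal(data, model="omm")

    def test_deterministic_given_seed(self, synthetic_day):
        a = gm.fit_meal(synthetic_day.meals[0], model="gom", seed=5, n_starts=2)
        b = gm.fit_meal(synthetic_day.meals[0], model="gom", seed=5, n_starts=2)
        np.testing.assert_array_equal(a.mode, b.mode)

    def test_laplace_agrees_with_mcmc_on_sg(self, synthetic_day):
        """Cross-check the Gaussian approximation against MCMC of the same kernel."""
        emcee = pytest.importorskip("emcee")
        data = synthetic_day.meals[0]
        fit = gm.fit_meal(data, model="gom", seed=0)
        pmap, obs = fit.param_map, fit.obs

        def logp(theta):
            return gm.log_joint(theta, data, pmap, obs)

        ndim = pmap.n
        nwalkers = 2 * ndim + 4
        rng = np.random.default_rng(42)
        p0 = fit.mode + 0.3 * np.sqrt(np.diag(fit.cov)) * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(nwalkers, ndim, logp)
        state = sampler.run_mcmc(p0, 300, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, 500, progress=False)
        chain = sampler.get_chain(flat=True)
        i = pmap.names.index("sg")
        sg_mcmc = math.exp(float(np.median(chain[:, i])))
        assert fit.medians["sg"] == pytest.approx(sg_mcmc, rel=0.10)


def _true_natural(truth):
    return {"p1": truth.p1, "p2": truth.p2, "sg": truth.sg, "beta": truth.beta,
            "T1": truth.ga.T1, "T2": truth.ga.T2, "W1": truth.ga.W1,
            "W2": truth.ga.W2, "RH": truth.ga.RH}


def _priors_at_truth(truth):
    priors = gm.default_gom_priors()
    out = {}
    for name, tv in _true_natural(truth).items():
        out[name] = gm.ParamPrior(tv, priors[name].cv, transform=priors[name].transform)
    return out


class TestChainDay:
    def test_first_meal_has_no_persisting_ga(self, synthetic_day):
        fits = gm.chain_day(synthetic_day.meals[:1], model="gom", seed=0)
        assert fits[0].rap is None or fits[0].rap.rate(100.0) == 0.0

    def test_later_meals_inherit_state_and_tail(self, synthetic_day):
        fits = gm.chain_day(synthetic_day.meals, model="gom", seed=0, n_starts=3)
        assert all(f is not None for f in fits)
        # meal 2 starts from the chained state, not the fasting state
        assert fits[1].param_map.x0 > 0.0
        assert fits[1].rap.rate(0.0) > 0.0
        # basal level is shared across the day
        assert fits[1].param_map.gb == fits[0].param_map.gb

    def test_decayed_tail_matches_isolated_fit(self):
        """When meal-1 GA has fully decayed by 240 min, chaining is a no-op."""
        subject = gm.draw_subject(23, meal_type="STAND", subject_id="S23")
        # force an early, narrow GA so the tail at 240 min is negligible
        ga = gm.RaLN(A=subject.true_gom.ga.A, RH=0.2, T1=20.0, W1=0.1,
                     T2=60.0, W2=0.1)
        from dataclasses import replace
        truth = replace(subject.true_gom, ga=ga, sg=4e-4, beta=30.0, p2=0.04)
        subject = gm.SyntheticSubject(
            subject_id="S23", sex=subject.sex, body_weight=subject.body_weight,
            meal_type="STAND", true_gom=truth, true_omm=subject.true_omm,
            meals=subject.meals, config=subject.config)
        day = gm.make_day(subject, noise_cv=0.01, seed=9)
        assert truth.ga.rate(240.0) < 1e-4

        chained = gm.chain_day(day.meals[:2], model="gom", seed=0, n_starts=3,
                               noise_cv=0.01)
        meal2 = day.meals[1]
        isolated = gm.fit_meal(meal2, model="gom", seed=0, n_starts=3,
                               noise_cv=0.01, gb=chained[0].param_map.gb)
        for name in ("sg", "p1", "p2"):
            assert chained[1].medians[name] == pytest.approx(
                isolated.medians[name], rel=0.05), name

    def test_three_identical_meals_agree_on_sg(self, synthetic_day):
        fits = gm.chain_day(synthetic_day.meals, model="gom", seed=0, n_starts=3)
        sgs = np.array([f.medians["sg"] for f in fits])
        cvs = np.array([f.cvs["sg"] for f in fits])
        pooled = np.sqrt(np.mean(cvs**2))
        spread = sgs.std() / sgs.mean()
        # the three estimates of one true SG agree within the pooled
        # posterior uncertainty (up to a 2-sigma allowance)
        assert spread < 2.0 * pooled
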