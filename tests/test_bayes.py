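"""Calibration tests: likelihood arithmetic, the proposal rule, chain
reproducibility, a conjugate linear-Gaussian check, and predictive bands."""

import numpy as np
import pytest
from scipy import stats

from socflux.bayes import (MCMCConfig, ObservationSet, StudyDesign,
                           log_likelihood, posterior_predictive, propose,
                           run_mcmc)
from socflux.models import initial_pool_state, simulate

from conftest import ADDED, SOC, TRUTH, make_observations


def _trajectories(truth=TRUTH, times=None):
    times = np.linspace(0, 70, 71) if times is None else times
    trt = simulate("interactive", truth,
                   initial_pool_state("interactive", truth, SOC, ADDED),
                   times=times)
    ctl = simulate("interactive", truth,
                   initial_pool_state("interactive", truth, SOC, 0.0),
                   times=times)
    return trt, ctl


class TestLogLikelihood:
    def test_perfect_fit_scores_zero(self, toy_obs):
        trt, ctl = _trajectories()
        assert log_likelihood(trt, toy_obs, ctl) == pytest.approx(0.0, abs=1e-4)

    def test_single_point_one_sigma_off_scores_minus_half(self):
        trt, ctl = _trajectories()
        t = 35.0
        x = float(trt.series_at(trt.co2_labeled, t))
        obs = ObservationSet("one", soc=SOC, added_c=ADDED, series={
            "new_treatment": np.array([[t, x + 0.02, 0.02]])})
        assert log_likelihood(trt, obs) == pytest.approx(-0.5)

    def test_matches_bruteforce_summation(self, noisy_obs):
        trt, ctl = _trajectories()
        expected = 0.0
        for nm, arr in noisy_obs.series.items():
            traj = ctl if nm == "old_control" else trt
            series = (traj.co2_labeled if nm == "new_treatment"
                      else traj.co2_unlabeled)
            for t, z, sd in arr:
                x = float(traj.series_at(series, t))
                expected += -((z - x) ** 2) / (2 * sd ** 2)
        assert log_likelihood(trt, noisy_obs, ctl) == pytest.approx(
            expected, abs=1e-12)

    def test_invariant_to_observation_order(self, noisy_obs):
        trt, ctl = _trajectories()
        shuffled = {nm: arr[::-1].copy() for nm, arr in noisy_obs.series.items()}
        obs2 = ObservationSet(noisy_obs.study_id, soc=SOC, added_c=ADDED,
                              series=shuffled)
        assert log_likelihood(trt, obs2, ctl) == pytest.approx(
            log_likelihood(trt, noisy_obs, ctl), abs=1e-12)

    def test_missing_sd_falls_back_with_warning(self):
        trt, ctl = _trajectories()
        obs = ObservationSet("nosd", soc=SOC, added_c=ADDED, series={
            "new_treatment": np.array([[35.0, 0.5, np.nan], [70.0, 0.6, 0.0]])})
        with pytest.warns(UserWarning, match="SDs replaced"):
            ll = log_likelihood(trt, obs)
        assert np.isfinite(ll)


class TestPropose:
    BOUNDS = np.array([[0.0, 1.0], [10.0, 30.0]])

    def test_stays_within_bounds(self):
        rng = np.random.default_rng(0)
        theta = np.array([0.99, 10.5])
        for _ in range(500):
            new = propose(theta, self.BOUNDS, 2.0, rng)
            assert np.all(new >= self.BOUNDS[:, 0] - 1e-12)
            assert np.all(new <= self.BOUNDS[:, 1] + 1e-12)

    def test_reflection_at_upper_bound(self):
        class TopStep:
            def uniform(self, lo, hi, size=None):
                return np.full(size, hi)  # d = +0.5 in every coordinate

        theta = self.BOUNDS[:, 1].astype(float)
        new = propose(theta, self.BOUNDS, 5.0, TopStep())
        span = self.BOUNDS[:, 1] - self.BOUNDS[:, 0]
        assert new == pytest.approx(self.BOUNDS[:, 1] - 0.1 * span)

    def test_step_distribution_is_uniform_window(self):
        # interior start far from bounds: no reflection, so the step is
        # exactly uniform with width (hi - lo) / D
        rng = np.random.default_rng(11)
        bounds = np.array([[0.0, 1.0]])
        d_div = 5.0
        theta = np.array([0.5])
        steps = np.array([propose(theta, bounds, d_div, rng)[0] - 0.5
                          for _ in range(100_000)])
        width = 1.0 / d_div
        assert stats.kstest(steps, stats.uniform(-width / 2, width).cdf).pvalue > 0.01


class TestRunMcmc:
    def test_same_seed_gives_identical_chain(self, toy_obs, short_mcmc,
                                             toy_chain):
        again = run_mcmc("interactive", toy_obs, short_mcmc)
        assert np.array_equal(toy_chain.samples, again.samples)
        assert np.array_equal(toy_chain.log_likelihoods,
                              again.log_likelihoods)

    def test_noise_free_fit_lands_on_truth(self, toy_chain):
        # noise-free data: the MLE must essentially reproduce the generator
        for name in ("K_N", "r", "f_N"):
            assert toy_chain.mle[name] == pytest.approx(TRUTH[name], rel=0.05)
        assert toy_chain.mle_log_likelihood > -5.0

    def test_rejects_study_violating_selection_criteria(self):
        bad = make_observations(times=np.array([5.0, 10.0, 20.0]))  # 20 d span
        with pytest.raises(ValueError, match="selection criteria"):
            run_mcmc("interactive", bad, MCMCConfig(n_iterations=1000))

    def test_samples_respect_prior_bounds(self, toy_chain):
        from socflux.models import get_model

        b = get_model("interactive").bounds_array()
        assert np.all(toy_chain.samples >= b[:, 0] - 1e-12)
        assert np.all(toy_chain.samples <= b[:, 1] + 1e-12)

    def test_linear_gaussian_posterior_matches_conjugate_analytic(self):
        """With every parameter pinned except r, the modeled new-C CO2 is
        affine in r, so the posterior is a (truncated) Gaussian computable in
        closed form."""
        times = np.array([10.0, 30.0, 70.0])
        obs0 = make_observations(times=times)
        pin = {n: (TRUTH[n], TRUTH[n]) for n in
               ("K_N", "K_O", "K_p", "p", "f_N")}
        design = StudyDesign("interactive", obs0)
        th0 = design.theta_vector(dict(TRUTH, r=0.0))
        th1 = design.theta_vector(dict(TRUTH, r=1.0))
        names = design.spec.parameter_names
        r_idx = names.index("r")
        x0 = {nm: v for nm, v in design.modeled_series(
            dict(zip(names, th0))).items()}
        x1 = {nm: v for nm, v in design.modeled_series(
            dict(zip(names, th1))).items()}
        # Gaussian posterior for r from sum over all points of the three series
        zs, sds, a, b = [], [], [], []
        for nm, arr in obs0.series.items():
            z = make_observations(times=times).values(nm)
            sd = np.full_like(z, 0.01)
            zs.append(z), sds.append(sd)
            a.append(x0[nm]), b.append(x1[nm] - x0[nm])
        z = np.concatenate(zs); sd = np.concatenate(sds)
        a = np.concatenate(a); b = np.concatenate(b)
        keep = np.abs(b) > 1e-14
        prec = np.sum(b[keep] ** 2 / sd[keep] ** 2)
        mean_analytic = np.sum(b[keep] * (z[keep] - a[keep]) / sd[keep] ** 2) / prec
        sd_analytic = 1.0 / np.sqrt(prec)

        series = {nm: np.c_[times, make_observations(times=times).values(nm),
                            np.full(times.size, 0.01)]
                  for nm in obs0.series}
        obs = ObservationSet("lin", soc=SOC, added_c=ADDED, series=series)
        chain = run_mcmc("interactive", obs, MCMCConfig(
            n_iterations=20_000, seed=3, bounds=pin))
        r_samp = chain.samples[:, r_idx]
        ess_guess = 200.0  # conservative for an autocorrelated walk
        assert r_samp.mean() == pytest.approx(
            mean_analytic, abs=4 * sd_analytic / np.sqrt(ess_guess) + 1e-4)
        assert r_samp.std() == pytest.approx(sd_analytic, rel=0.3)
        # split-half stationarity: the two halves agree within Monte-Carlo error
        half = r_samp.size // 2
        se = r_samp.std() / np.sqrt(ess_guess / 2)
        assert abs(r_samp[:half].mean() - r_samp[half:].mean()) < 3 * se


class TestPosteriorPredictive:
    def test_degenerate_chain_gives_zero_width_band(self, toy_obs, toy_chain):
        from dataclasses import replace

        one = toy_chain.samples[np.argmax(toy_chain.log_likelihoods)]
        degen = replace(toy_chain,
                        samples=np.tile(one, (50, 1)),
                        log_likelihoods=np.full(50, toy_chain.mle_log_likelihood))
        bands = posterior_predictive(degen, "interactive", toy_obs)
        for nm, entry in bands.items():
            assert entry[0.025] == pytest.approx(entry[0.975], abs=1e-12)

    def test_bands_widen_when_posterior_dispersion_grows(self, toy_obs,
                                                         toy_chain):
        from dataclasses import replace

        from socflux.models import get_model

        base = posterior_predictive(toy_chain, "interactive", toy_obs,
                                    max_samples=10 ** 9)
        # inflate the samples threefold around the best sample: strictly
        # more parameter dispersion, same center
        mode = toy_chain.samples[np.argmax(toy_chain.log_likelihoods)]
        b = get_model("interactive").bounds_array()
        inflated = np.clip(mode + 3.0 * (toy_chain.samples - mode),
                           b[:, 0], b[:, 1])
        aug = replace(toy_chain,
                      samples=np.vstack([toy_chain.samples, inflated]),
                      log_likelihoods=np.concatenate(
                          [toy_chain.log_likelihoods] * 2))
        wide = posterior_predictive(aug, "interactive", toy_obs,
                                    max_samples=10 ** 9)
        for nm in base:
            w0 = base[nm][0.975] - base[nm][0.025]
            w1 = wide[nm][0.975] - wide[nm][0.025]
            assert w1.mean() >= w0.mean()
            assert np.all(w1 >= w0 - 1e-3)  # pointwise, up to sim tolerance

    def test_quantiles_validated(self, toy_obs, toy_chain):
        with pytest.raises(ValueError):
            posterior_predictive(toy_chain, "interactive", toy_obs,
                                 quantiles=(0.0, 0.975))
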