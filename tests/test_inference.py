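"""Tests for the loss, point estimation, ABC-SMC and posterior summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinbind import ParameterVector
from kinbind.inference import (PosteriorSample, PriorSpec, abc_smc,
                               default_abc_subset, fit_point_estimate, loss,
                               posterior_summary, relative_error,
                               simulate_condition_means)


def one_condition_frame(mean, sem=0.1, length=45.0, gap=0.0, n=40):
    return pd.DataFrame([{"length_nm": length, "gap_nm": gap,
                          "mean_time_s": mean, "sem_s": sem, "n": n}])


class TestLoss:
    def test_zero_when_observations_match_simulation(self, adp_params):
        frame = one_condition_frame(1.0)
        sim = simulate_condition_means(adp_params, frame, S=20, seed=5)
        frame["mean_time_s"] = sim
        assert loss(adp_params, frame, S=20, seed=5) == 0.0

    def test_unit_offset_gives_unit_loss(self, adp_params):
        frame = one_condition_frame(1.0)
        sim = simulate_condition_means(adp_params, frame, S=20, seed=5)
        frame["mean_time_s"] = sim - 1.0
        assert loss(adp_params, frame, S=20, seed=5) == pytest.approx(1.0)

    def test_self_generated_data_leaves_sampling_noise(self, adp_params,
                                                       fast_summary):
        val = loss(adp_params, fast_summary, S=40, seed=9)
        sem2 = (fast_summary.sem_s ** 2).sum()
        assert 0 < val < 50 * sem2

    def test_invariant_to_condition_ordering(self, adp_params,
                                             fast_summary):
        shuffled = fast_summary.sample(frac=1.0, random_state=1)
        assert (loss(adp_params, fast_summary, S=10, seed=3)
                == loss(adp_params, shuffled, S=10, seed=3))

    def test_sem_weighting_rescales_residuals(self, adp_params):
        frame = one_condition_frame(1.0, sem=0.5)
        sim = simulate_condition_means(adp_params, frame, S=10, seed=5)
        frame["mean_time_s"] = sim - 1.0
        w = loss(adp_params, frame, S=10, seed=5, weights="sem")
        assert w == pytest.approx(1.0 / 0.25)

    def test_empty_dataset_rejected(self, adp_params):
        with pytest.raises(ValueError):
            loss(adp_params, one_condition_frame(1.0).iloc[0:0])


class TestRelativeError:
    def test_identical_means(self):
        assert relative_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_condition_arithmetic(self):
        assert relative_error([1.5], [1.0]) == pytest.approx(0.5)

    def test_sum_convention_over_three_conditions(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert relative_error(obs * 1.2, obs) == pytest.approx(0.6)
        assert relative_error(obs * 1.2, obs, agg="mean") == pytest.approx(
            0.2)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(ValueError):
            relative_error([1.0], [0.0])


class TestPointEstimate:
    def test_one_parameter_recovery_within_factor_two(self, adp_params,
                                                      fast_summary):
        fit = fit_point_estimate(
            fast_summary, {"k_off_adp_fast": (0.2, 20.0)}, budget=30,
            S=25, seed=4, base_params=adp_params)
        ratio = fit.params.k_off_adp_fast / adp_params.k_off_adp_fast
        assert 0.5 <= ratio <= 2.0

    def test_trace_is_best_so_far(self, adp_params, fast_summary):
        fit = fit_point_estimate(
            fast_summary, {"k_off_adp_fast": (0.2, 20.0)}, budget=20,
            S=10, seed=1, base_params=adp_params)
        trace = np.array(fit.loss_trace)
        assert (np.diff(trace) <= 1e-12).all()
        assert fit.best_loss == trace[-1]

    def test_budget_below_initial_design_rejected(self, adp_params,
                                                  fast_summary):
        with pytest.raises(ValueError, match="initial design"):
            fit_point_estimate(
                fast_summary, {n: (0.1, 10.0) for n in
                               ParameterVector.FREE_NAMES},
                budget=10, S=5, seed=0, base_params=adp_params)

    def test_local_refinement_requires_start(self, adp_params,
                                             fast_summary):
        with pytest.raises(ValueError, match="x0"):
            fit_point_estimate(fast_summary, {"D_m": (500, 5000)},
                               budget=20, S=5, seed=0,
                               base_params=adp_params, local_only=True)


class TestPriors:
    def test_natural_scale_moments(self):
        priors = PriorSpec({"k_on_adp": (1000.0, 100.0)})
        rng = np.random.default_rng(0)
        draws = np.exp(priors.sample_log(rng, size=20000)[:, 0])
        assert draws.mean() == pytest.approx(1000.0, rel=0.02)
        assert draws.std() == pytest.approx(100.0, rel=0.05)

    def test_central_interval_contains_median(self):
        priors = PriorSpec()
        lo, hi = priors.central_interval("D_m", 0.5)
        assert lo < 10 ** 3.3 < hi


class TestAbcSmc:
    def test_vacuous_threshold_returns_prior_draws(self, fast_summary):
        priors = PriorSpec()
        gens = abc_smc(fast_summary.iloc[:1], priors, n_particles=200,
                       schedule=[math.inf], S=1, seed=5)
        g = gens[0]
        assert np.allclose(g.weights, 1.0 / len(g.weights))
        mean_log = g.log_particles.mean(axis=0)
        # i.i.d. prior draws: sample mean within 4 standard errors
        se = priors.sigma / math.sqrt(len(g.weights))
        assert np.all(np.abs(mean_log - priors.mu) < 4 * se)

    def test_weights_normalized_each_generation(self, fast_summary):
        sub = default_abc_subset(fast_summary)
        gens = abc_smc(sub, PriorSpec(), n_particles=10,
                       schedule=[1.8, 1.4], S=5, seed=2)
        for g in gens:
            assert g.weights.sum() == pytest.approx(1.0)

    def test_posterior_spread_never_exceeds_the_prior(self, fast_summary):
        priors = PriorSpec()
        sub = default_abc_subset(fast_summary)
        gens = abc_smc(sub, priors, n_particles=20,
                       schedule=[1.8, 1.0], S=10, seed=6)
        g = gens[-1]
        mean = np.average(g.log_particles, axis=0, weights=g.weights)
        v_last = np.average((g.log_particles - mean) ** 2, axis=0,
                            weights=g.weights)
        # weighted filtering can only concentrate relative to the prior
        assert np.all(v_last <= priors.sigma ** 2 * 1.5)  # MC allowance

    def test_prior_data_conflict_stalls_with_diagnostics(self):
        frame = pd.DataFrame([
            {"length_nm": L, "gap_nm": 0.0, "mean_time_s": 90.0,
             "sem_s": 1.0, "n": 40} for L in (33.0, 45.0, 60.0)])
        gens = abc_smc(frame, PriorSpec(), n_particles=10,
                       schedule=[1.8], S=3, seed=8,
                       max_draws_per_generation=30)
        assert gens[-1].stalled
        assert gens[-1].n_draws == 30

    def test_nonmonotone_schedule_rejected(self, fast_summary):
        with pytest.raises(ValueError):
            abc_smc(fast_summary, PriorSpec(), schedule=[1.0, 1.4], seed=0)


class TestPosteriorSummary:
    def _sample_from(self, values, names=("D_m",), seed=0):
        rng = np.random.default_rng(seed)
        logp = np.log(np.asarray(values))[:, None]
        w = np.full(len(values), 1.0 / len(values))
        return PosteriorSample(particles=np.exp(logp), log_particles=logp,
                               weights=w, names=list(names), generation=1,
                               epsilon=1.0, n_draws=len(values))

    def test_map_tracks_a_jittered_point_mass(self):
        rng = np.random.default_rng(3)
        vals = 2000.0 * np.exp(rng.normal(0, 0.01, size=200))
        summ = posterior_summary(self._sample_from(vals))
        assert summ["D_m"]["map"] == pytest.approx(2000.0, rel=0.05)
        assert summ["D_m"]["median"] == pytest.approx(2000.0, rel=0.05)

    def test_prior_samples_recover_prior_density(self):
        priors = PriorSpec({"D_m": (10 ** 3.3, 100.0)})
        rng = np.random.default_rng(4)
        logp = priors.sample_log(rng, size=4000)
        sample = PosteriorSample(
            particles=np.exp(logp), log_particles=logp,
            weights=np.full(4000, 1 / 4000), names=["D_m"], generation=1,
            epsilon=math.inf, n_draws=4000)
        summ = posterior_summary(sample)
        grid = summ["D_m"]["kde_grid_log"]
        kde = summ["D_m"]["kde_density_log"]
        prior_pdf = stats.norm.pdf(grid, priors.mu[0], priors.sigma[0])
        l1 = np.trapezoid(np.abs(kde - prior_pdf), grid)
        assert l1 < 0.1

    def test_degenerate_particles_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            posterior_summary(self._sample_from([5.0, 5.0, 5.0]))
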