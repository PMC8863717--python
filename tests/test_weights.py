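"""Weight estimators: conflict regressions and the posterior model fit."""

import numpy as np
import pytest

from cuebias import (
    ObserverParams,
    PrecisionEstimate,
    SamplerConfig,
    behavioral_weight_multiple,
    behavioral_weight_simple,
    fit_central_tendency_model,
    optimal_weight_prediction,
    simulate_trials,
)
from cuebias.weights import log_posterior, split_rhat


def biased_noiseless_responses(pairs, w1, w_p, mu):
    """Deterministic responses of a biased observer with exact sensory estimates."""
    s1, s2 = pairs[:, 0], pairs[:, 1]
    return (1 - w_p) * (w1 * s1 + (1 - w1) * s2) + w_p * mu


class TestBehavioralSimple:
    def test_exact_weight_without_bias(self, conflict_pairs):
        s1, s2 = conflict_pairs[:, 0], conflict_pairs[:, 1]
        r = 0.3 * s1 + 0.7 * s2
        est = behavioral_weight_simple(s1, s2, r)
        assert est.w1 == pytest.approx(0.3, abs=1e-12)
        assert est.extras["w2_implicit"] == pytest.approx(0.7, abs=1e-12)

    def test_bias_attenuates_toward_half(self, conflict_pairs):
        """On the balanced 72-pair design the noiseless estimand is
        (1 - w_p) * w1 + w_p / 2, confirmed against the exact OLS solution."""
        w1, w_p, mu = 0.8, 0.5, 0.5
        r = biased_noiseless_responses(conflict_pairs, w1, w_p, mu)
        s1, s2 = conflict_pairs[:, 0], conflict_pairs[:, 1]
        est = behavioral_weight_simple(s1, s2, r)
        # independent oracle: polyfit of (r - s2) on (s1 - s2)
        slope_oracle = np.polyfit(s1 - s2, r - s2, 1)[0]
        assert est.w1 == pytest.approx(slope_oracle, abs=1e-10)
        assert est.w1 == pytest.approx((1 - w_p) * w1 + w_p / 2, abs=1e-10)
        assert est.w1 == pytest.approx(0.65, abs=1e-10)

    def test_underestimates_best_cue_weight_of_bayesian_observer(self, conflict_pairs):
        params = ObserverParams(sigma1=0.05, sigma2=0.15, sigma_n=0.01, w_pc=0.5, mu=0.5)
        true_w1 = params.weights[0]
        assert true_w1 > 0.5
        trials = simulate_trials(params, "both", conflict_pairs=conflict_pairs,
                                 reps=10, seed=71)
        est = behavioral_weight_simple(trials["s1"], trials["s2"], trials["response"])
        assert est.w1 < true_w1 - 3 * est.uncertainty

    def test_zero_conflict_variance_rejected(self):
        s1 = np.array([0.4, 0.5, 0.6])
        s2 = s1 + 0.1
        with pytest.raises(ValueError):
            behavioral_weight_simple(s1, s2, s1)


class TestBehavioralMultiple:
    def test_exact_coefficients_without_bias(self, conflict_pairs):
        s1, s2 = conflict_pairs[:, 0], conflict_pairs[:, 1]
        r = 0.3 * s1 + 0.7 * s2
        est = behavioral_weight_multiple(s1, s2, r)
        assert est.w1 == pytest.approx(0.3, abs=1e-10)
        assert est.extras["w2"] == pytest.approx(0.7, abs=1e-10)

    def test_bias_shrinks_both_coefficients(self, conflict_pairs):
        """Noiseless biased data give ((1-w_p)w1, (1-w_p)w2): the sum drops below 1."""
        w1, w_p, mu = 0.8, 0.4, 0.5
        r = biased_noiseless_responses(conflict_pairs, w1, w_p, mu)
        s1, s2 = conflict_pairs[:, 0], conflict_pairs[:, 1]
        est = behavioral_weight_multiple(s1, s2, r)
        assert est.w1 == pytest.approx((1 - w_p) * w1, abs=1e-10)
        assert est.extras["w2"] == pytest.approx((1 - w_p) * (1 - w1), abs=1e-10)
        assert est.w1 + est.extras["w2"] < 1.0

    def test_constant_responses_give_zero_weights(self, conflict_pairs):
        s1, s2 = conflict_pairs[:, 0], conflict_pairs[:, 1]
        est = behavioral_weight_multiple(s1, s2, np.full(len(s1), 0.5))
        assert est.w1 == pytest.approx(0.0, abs=1e-10)
        assert est.extras["w2"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_predictors_rejected(self):
        s1 = np.linspace(0.4, 0.6, 10)
        with pytest.raises(ValueError):
            behavioral_weight_multiple(s1, s1, s1)


class TestOptimalWeightPrediction:
    def test_equal_precisions(self):
        a = PrecisionEstimate(kind="sensory", variance=3.0)
        b = PrecisionEstimate(kind="sensory", variance=3.0)
        assert optimal_weight_prediction(a, b) == pytest.approx(0.5)

    def test_reliability_weighting(self):
        a = PrecisionEstimate(kind="sensory", variance=4.0)
        b = PrecisionEstimate(kind="sensory", variance=12.0)
        assert optimal_weight_prediction(a, b) == pytest.approx(0.75)

    def test_kind_mismatch_rejected(self):
        a = PrecisionEstimate(kind="sensory", variance=4.0)
        b = PrecisionEstimate(kind="behavioral", variance=4.0)
        with pytest.raises(ValueError):
            optimal_weight_prediction(a, b)


class TestSplitRhat:
    def test_well_mixed_chains_are_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 1000))
        assert split_rhat(chains) < 1.02

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 1000)) + np.array([[0.0], [2.0], [4.0]])
        assert split_rhat(chains) > 1.5


@pytest.fixture(scope="module")
def recovery_trials(conflict_pairs):
    params = ObserverParams(sigma1=0.05, sigma2=0.05 * np.sqrt(3.0),
                            sigma_n=0.01, w_pc=0.3, mu=0.5)
    trials = simulate_trials(params, "both", conflict_pairs=conflict_pairs,
                             reps=10, seed=81)
    return params, trials


@pytest.fixture(scope="module")
def fitted(recovery_trials):
    params, trials = recovery_trials
    est = fit_central_tendency_model(trials, mu=0.5, config=SamplerConfig(seed=82))
    return params, est


class TestPosteriorFit:
    def test_recovers_true_weight_and_bias(self, fitted):
        params, est = fitted
        assert est.w1 == pytest.approx(params.weights[0], abs=0.05)
        assert est.extras["w_p"] == pytest.approx(params.w_pc, abs=0.05)

    def test_residual_sd_absorbs_shrunken_sensory_noise(self, fitted):
        params, est = fitted
        w1, w2 = params.weights
        expected_sd = np.sqrt((1 - params.w_pc) ** 2
                              * (w1**2 * params.sigma1**2 + w2**2 * params.sigma2**2)
                              + params.sigma_n**2)
        assert est.extras["sigma"] > params.sigma_n
        assert est.extras["sigma"] == pytest.approx(expected_sd, rel=0.15)

    def test_convergence_diagnostics_reported(self, fitted):
        _, est = fitted
        assert set(est.extras["rhat"]) == {"w1", "w_p", "sigma"}
        assert est.extras["converged"]
        assert all(r < 1.1 for r in est.extras["rhat"].values())

    def test_unbiased_case_matches_simple_regression(self, conflict_pairs):
        """With w_p = 0 the model nests the plain conflict regression."""
        params = ObserverParams(sigma1=0.05, sigma2=0.1, sigma_n=0.01, w_pc=0.0, mu=0.5)
        trials = simulate_trials(params, "both", conflict_pairs=conflict_pairs,
                                 reps=10, seed=83)
        beh = behavioral_weight_simple(trials["s1"], trials["s2"], trials["response"])
        sen = fit_central_tendency_model(trials, mu=0.5, config=SamplerConfig(seed=84))
        joint = 3 * np.hypot(beh.uncertainty, sen.uncertainty)
        assert abs(sen.w1 - beh.w1) < joint

    def test_posterior_mode_matches_grid_likelihood(self, conflict_pairs):
        """Brute-force grid maximum likelihood agrees within one grid cell."""
        params = ObserverParams(sigma1=0.05, sigma2=0.1, sigma_n=0.01, w_pc=0.4, mu=0.5)
        trials = simulate_trials(params, "both", conflict_pairs=conflict_pairs,
                                 reps=2, seed=85)
        s1 = trials["s1"].to_numpy()
        s2 = trials["s2"].to_numpy()
        r = trials["response"].to_numpy()
        w1_grid = np.linspace(0.0, 1.0, 21)
        wp_grid = np.linspace(0.0, 1.0, 21)
        sd_grid = np.geomspace(0.005, 0.2, 40)
        ll = np.empty((21, 21, 40))
        for i, w1 in enumerate(w1_grid):
            for j, wp in enumerate(wp_grid):
                mean = (1 - wp) * (w1 * s1 + (1 - w1) * s2) + wp * 0.5
                sse = np.sum((r - mean) ** 2)
                ll[i, j, :] = -r.size * np.log(sd_grid) - 0.5 * sse / sd_grid**2
        i, j, _ = np.unravel_index(np.argmax(ll), ll.shape)
        est = fit_central_tendency_model(trials, mu=0.5, config=SamplerConfig(seed=86))
        assert abs(est.w1 - w1_grid[i]) <= 0.05 + 1e-9
        assert abs(est.extras["w_p"] - wp_grid[j]) <= 0.05 + 1e-9

    def test_log_posterior_respects_prior_support(self, conflict_pairs):
        s1, s2 = conflict_pairs[:, 0], conflict_pairs[:, 1]
        r = 0.5 * (s1 + s2)
        assert log_posterior((1.2, 0.5, 0.1), s1, s2, r, 0.5) == -np.inf
        assert log_posterior((0.5, 0.5, 1.5), s1, s2, r, 0.5) == -np.inf
        assert np.isfinite(log_posterior((0.5, 0.5, 0.1), s1, s2, r, 0.5))

    def test_missing_cue_values_rejected(self, conflict_pairs):
        params = ObserverParams(sigma1=0.05, sigma2=0.1)
        trials = simulate_trials(params, "cue1", targets=[0.4, 0.5, 0.6], reps=5, seed=87)
        with pytest.raises(ValueError):
            fit_central_tendency_model(trials, mu=0.5)

    def test_deterministic_given_seed(self, recovery_trials):
        _, trials = recovery_trials
        cfg = SamplerConfig(seed=90, n_samples=100)
        a = fit_central_tendency_model(trials, mu=0.5, config=cfg)
        b = fit_central_tendency_model(trials, mu=0.5, config=cfg)
        assert a.w1 == b.w1
        np.testing.assert_array_equal(a.extras["samples"], b.extras["samples"])
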