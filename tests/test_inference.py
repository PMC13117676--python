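"""Estimators, likelihood, bootstrap, LRT and the Model/Results API."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from branchtrain import (
    GeometricRunModel,
    alpha_from_mean,
    bootstrap_estimate,
    estimate_alpha_mean,
    estimate_alpha_mle,
    log_likelihood,
    lrt_parametric_bootstrap,
    sample_from_lengths,
)

lengths_strategy = st.lists(st.integers(1, 30), min_size=1, max_size=50)


class TestMeanEstimator:
    @pytest.mark.parametrize(
        "mean,alpha",
        [(1.105, -0.405), (2.400, 0.083), (1.230, -0.313), (2.0, 0.0)],
    )
    def test_alpha_from_mean(self, mean, alpha):
        assert round(alpha_from_mean(mean, 0.5), 3) == pytest.approx(alpha)

    def test_all_singletons_hits_lower_boundary(self):
        sample = sample_from_lengths([1] * 10)
        assert estimate_alpha_mean(sample, 0.5).alpha_hat == pytest.approx(-0.5)

    def test_nonsymmetric_baseline(self):
        sample = sample_from_lengths([2, 2])
        est = estimate_alpha_mean(sample, 0.4)
        assert est.pjj_hat == pytest.approx(0.5)
        assert est.alpha_hat == pytest.approx(0.1)


class TestMLE:
    def test_small_sample(self):
        est = estimate_alpha_mle(sample_from_lengths([1, 1, 2]), 0.5)
        assert est.pjj_hat == pytest.approx(0.25)
        assert est.alpha_hat == pytest.approx(-0.25)

    def test_single_long_run(self):
        assert estimate_alpha_mle(sample_from_lengths([5]), 0.5).pjj_hat == (
            pytest.approx(0.8)
        )

    @given(lengths_strategy)
    @settings(max_examples=300, deadline=None)
    def test_equivalent_to_mean_estimator(self, lengths):
        sample = sample_from_lengths(lengths)
        a = estimate_alpha_mean(sample, 0.5).alpha_hat
        b = estimate_alpha_mle(sample, 0.5).alpha_hat
        assert abs(a - b) < 1e-12

    @given(lengths_strategy)
    @settings(max_examples=50, deadline=None)
    def test_maximizes_the_likelihood(self, lengths):
        sample = sample_from_lengths(lengths)
        qhat = estimate_alpha_mle(sample, 0.5).pjj_hat
        grid = np.linspace(0.0, 0.999, 1000)
        ll = [log_likelihood(sample, q) for q in grid]
        assert abs(grid[int(np.argmax(ll))] - qhat) <= 1.1e-3


class TestLogLikelihood:
    def test_singletons(self):
        assert log_likelihood(sample_from_lengths([1, 1]), 0.5) == pytest.approx(
            2 * math.log(0.5)
        )

    def test_term_by_term(self):
        assert log_likelihood([1, 1, 2], 0.25) == pytest.approx(
            math.log(0.25) + 3 * math.log(0.75)
        )

    def test_pjj_zero_convention(self):
        assert log_likelihood([1, 1, 1], 0.0) == 0.0
        assert log_likelihood([1, 2], 0.0) == -math.inf

    def test_pjj_one_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood([1, 2], 1.0)

    def test_censored_runs_contribute_survival_only(self):
        full = log_likelihood([3, 2], 0.4)
        cens = log_likelihood([3, 2], 0.4, censored=[False, True])
        assert cens == pytest.approx(full - math.log(0.6))


class TestBootstrap:
    def test_identical_runs_collapse(self):
        est = bootstrap_estimate(sample_from_lengths([2, 2, 2, 2]), B=200, seed=0)
        assert est.se == 0.0
        assert est.ci_low == est.ci_high == pytest.approx(est.alpha_hat)

    def test_deterministic_given_seed(self):
        sample = sample_from_lengths([1, 2, 1, 3, 1, 1, 2])
        a = bootstrap_estimate(sample, B=500, seed=7)
        b = bootstrap_estimate(sample, B=500, seed=7)
        assert (a.se, a.ci_low, a.ci_high) == (b.se, b.ci_low, b.ci_high)

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_ci_within_estimator_range(self, lengths):
        est = bootstrap_estimate(sample_from_lengths(lengths), B=300, seed=1)
        assert -0.5 <= est.ci_low <= est.alpha_hat <= est.ci_high < 0.5

    def test_singleton_dominated_sample_saturates_at_minus_half(self):
        # resamples that are all singletons pin the percentile lower limit
        sample = sample_from_lengths([1] * 17 + [2, 2])
        est = bootstrap_estimate(sample, B=2000, seed=3)
        assert est.ci_low == pytest.approx(-0.5)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_estimate(sample_from_lengths([3]), B=100, seed=0)


class TestLRT:
    def test_lambda_zero_at_null_mle(self):
        # sum(n_i - 1)/sum(n_i) = 0.5 exactly -> deviance 0, p-value ~ 1
        res = lrt_parametric_bootstrap(sample_from_lengths([2, 2]), B=499, seed=0)
        assert res.lambda_obs == 0.0
        assert res.p_value > 0.5

    def test_p_value_floor(self):
        sample = sample_from_lengths([1] * 60)
        res = lrt_parametric_bootstrap(sample, B=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_strong_alternation_is_significant(self):
        sample = sample_from_lengths([1] * 21)
        res = lrt_parametric_bootstrap(sample, B=999, seed=5)
        assert res.p_value < 0.01

    def test_deterministic_given_seed(self):
        sample = sample_from_lengths([1, 1, 2, 1, 3, 1])
        a = lrt_parametric_bootstrap(sample, B=299, seed=2)
        b = lrt_parametric_bootstrap(sample, B=299, seed=2)
        assert a.p_value == b.p_value
        assert np.array_equal(a.replicates, b.replicates)

    def test_p_value_decreases_with_effect_size(self):
        weak = lrt_parametric_bootstrap(
            sample_from_lengths([1, 2] * 10), B=999, seed=9
        )
        strong = lrt_parametric_bootstrap(sample_from_lengths([1] * 20), B=999, seed=9)
        assert strong.p_value < weak.p_value


class TestParameterRecovery:
    @pytest.mark.parametrize("alpha", [-0.3, 0.0, 0.2])
    def test_pooled_estimate_converges(self, alpha):
        rng = np.random.default_rng(int((alpha + 1) * 100))
        q = 0.5 + alpha
        lengths = rng.geometric(1 - q, size=4000)
        est = estimate_alpha_mean(sample_from_lengths(lengths), 0.5)
        se = (1 - q) * np.sqrt(q / 4000)
        assert abs(est.alpha_hat - alpha) < 4 * se


class TestModelAPI:
    def test_from_sequences_and_fit(self, make_seq):
        trains = [make_seq("LLRRRL"), make_seq("LRRL", "t2")]
        res = GeometricRunModel.from_sequences(trains, "rear_pooled").fit(
            bootstrap=500, seed=0
        )
        assert res.M == 4
        assert res.alpha_hat == pytest.approx(1 - 4 / 7 - 0.5)
        lo, hi = res.conf_int()
        assert lo <= res.alpha_hat <= hi

    def test_point_fit_has_no_ci(self):
        res = GeometricRunModel.from_lengths([1, 2, 3]).fit(bootstrap=0)
        assert res.se is None
        with pytest.raises(ValueError):
            res.conf_int()

    def test_loglike_matches_function(self):
        model = GeometricRunModel.from_lengths([1, 1, 2])
        assert model.loglike(0.25) == pytest.approx(
            log_likelihood([1, 1, 2], 0.25)
        )

    def test_summary_reports_estimate(self):
        res = GeometricRunModel.from_lengths([1] * 17 + [2, 2], group="front").fit(
            bootstrap=1000, seed=0
        )
        text = res.summary()
        assert "front" in text
        assert "-0.405" in text
        assert "1.105" in text

    def test_results_expose_lrt(self):
        res = GeometricRunModel.from_lengths([1, 1, 1, 1, 2]).fit(bootstrap=0)
        lrt = res.lrt(B=199, seed=1)
        assert lrt.B == 199 and 0 < lrt.p_value <= 1
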