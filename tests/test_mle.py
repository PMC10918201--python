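"""Censored ML estimation: closed forms, recovery, SEs, batch parity."""

import numpy as np
import pytest

from survselect import (
    DistributionSpec,
    EstimationError,
    SurvivalSample,
    calibrate_censoring,
    fit,
    fit_batch,
    fit_exponential,
    fit_genexp,
    fit_weibull,
    generate_censored_sample,
    median,
    median_gradient,
    quantile,
)

LN2 = np.log(2.0)


def simulate_matrix(spec, reps, n, seed, censoring=0.0):
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=(reps, n))
    t = quantile(spec, np.clip(u, 1e-12, None))
    if censoring == 0.0:
        return t, np.ones_like(t)
    plan = calibrate_censoring(spec, censoring)
    c = rng.exponential(1.0 / plan.censor_rate, size=(reps, n))
    return np.minimum(t, c), (t <= c).astype(float)


class TestExponential:
    def test_closed_form(self):
        est = fit_exponential(SurvivalSample([1, 2, 3, 4], [1, 1, 1, 1]))
        assert est.rate_hat == pytest.approx(0.4, rel=1e-12)
        assert est.median_hat == pytest.approx(LN2 / 0.4, rel=1e-12)
        assert est.se_median == pytest.approx(est.median_hat / 2.0, rel=1e-12)
        assert est.loglik == pytest.approx(4 * np.log(0.4) - 0.4 * 10, rel=1e-12)
        assert est.converged

    def test_censored_rate_uses_r_over_w(self):
        est = fit_exponential(SurvivalSample([1, 2, 3, 4], [1, 0, 1, 0]))
        assert est.rate_hat == pytest.approx(2 / 10)

    def test_all_censored_errors(self):
        with pytest.raises(EstimationError):
            fit_exponential(SurvivalSample([1.0, 2.0], [0, 0]))

    def test_simulation_recovery(self):
        spec = DistributionSpec("exponential", rate=0.1)
        rng = np.random.default_rng(2)
        s = SurvivalSample(quantile(spec, rng.uniform(1e-9, 1, 2000)), np.ones(2000))
        est = fit_exponential(s)
        assert est.rate_hat == pytest.approx(0.1, abs=0.007)


class TestWeibull:
    def test_fixed_shape_one_equals_exponential_mle(self):
        s = SurvivalSample([2.0, 5.0, 1.0, 7.0, 3.0], np.ones(5, dtype=int))
        est = fit_weibull(s, fixed_shape=1.0)
        assert est.rate_hat == pytest.approx(5 / 18.0, rel=1e-10)

    def test_recovery_of_median(self):
        spec = DistributionSpec("weibull", rate=0.10, shape=2.0)
        plan = calibrate_censoring(spec, 0.0)
        est = fit_weibull(generate_censored_sample(spec, plan, 500, seed=4))
        # single fit lands within its own sampling error of the truth ...
        assert abs(est.median_hat - 8.3255) < 4 * est.se_median
        assert est.converged
        # ... and the estimator is unbiased in the mean over replicates
        u, d = simulate_matrix(spec, 100, 500, seed=4)
        batch = fit_batch("weibull", u, d)
        assert batch.median[batch.ok].mean() == pytest.approx(8.3255, abs=0.1)

    def test_needs_two_distinct_events(self):
        with pytest.raises(EstimationError):
            fit_weibull(SurvivalSample([3.0, 3.0, 5.0], [1, 1, 0]))
        with pytest.raises(EstimationError):
            fit_weibull(SurvivalSample([3.0, 5.0], [1, 0]))

    def test_se_against_bootstrap(self):
        """Delta-method SE vs a 500-resample bootstrap at n=200."""
        spec = DistributionSpec("weibull", rate=0.10, shape=2.0)
        sample = generate_censored_sample(spec, calibrate_censoring(spec, 0.0), 200, seed=8)
        est = fit_weibull(sample)
        rng = np.random.default_rng(9)
        idx = rng.integers(0, 200, size=(500, 200))
        boot = fit_batch("weibull", sample.times[idx], sample.events[idx].astype(float))
        boot_se = np.std(boot.median[boot.ok], ddof=1)
        assert 0.8 < est.se_median / boot_se < 1.2


class TestGenexp:
    def test_fixed_shape_one_equals_exponential_mle(self):
        s = SurvivalSample([2.0, 5.0, 1.0, 7.0, 3.0], np.ones(5, dtype=int))
        est = fit_genexp(s, fixed_shape=1.0)
        assert est.rate_hat == pytest.approx(5 / 18.0, rel=1e-5)

    def test_recovery_of_median(self):
        spec = DistributionSpec("genexp", rate=0.09, shape=2.4)
        plan = calibrate_censoring(spec, 0.0)
        est = fit_genexp(generate_censored_sample(spec, plan, 500, seed=6))
        assert abs(est.median_hat - median(spec)) / median(spec) < 0.10
        assert est.converged

    def test_loglik_at_mle_dominates_truth(self):
        from survselect.mle import _gexp_loglik

        spec = DistributionSpec("genexp", rate=0.10, shape=2.0)
        sample = generate_censored_sample(
            spec, calibrate_censoring(spec, 0.2), 300, seed=12
        )
        est = fit_genexp(sample)
        ll_true = float(
            _gexp_loglik(2.0, 0.10, sample.times, sample.events.astype(float))
        )
        assert est.loglik >= ll_true


class TestMedianGradient:
    @pytest.mark.parametrize(
        "family,shape,rate",
        [
            ("exponential", 1.0, 0.2),
            ("weibull", 2.0, 0.10),
            ("weibull", 0.7, 0.30),
            ("genexp", 2.0, 0.10),
            ("genexp", 0.5, 0.05),
        ],
    )
    def test_matches_finite_differences(self, family, shape, rate):
        g_a, g_t = median_gradient(family, shape, rate)

        def mu(a, t):
            return median(
                DistributionSpec(family, rate=t, shape=1.0 if family == "exponential" else a)
            )

        h = 1e-6
        if family != "exponential":
            fd_a = (mu(shape + h, rate) - mu(shape - h, rate)) / (2 * h)
            assert g_a == pytest.approx(fd_a, rel=1e-5)
        fd_t = (mu(shape, rate + h * rate) - mu(shape, rate - h * rate)) / (2 * h * rate)
        assert g_t == pytest.approx(fd_t, rel=1e-5)

    @pytest.mark.parametrize("family", ["weibull", "genexp"])
    def test_rate_component_is_minus_mu_over_theta(self, family):
        spec = DistributionSpec(family, rate=0.1, shape=2.0)
        _, g_t = median_gradient(family, 2.0, 0.1)
        assert g_t == pytest.approx(-median(spec) / 0.1, rel=1e-12)


class TestInvariance:
    @pytest.mark.parametrize("family", ["exponential", "weibull", "genexp"])
    def test_median_hat_equals_closed_form_at_fit(self, family):
        spec = DistributionSpec(family, rate=0.1, shape=1.0 if family == "exponential" else 2.0)
        sample = generate_censored_sample(
            spec, calibrate_censoring(spec, 0.1), 150, seed=14
        )
        est = fit(sample, family)
        refit_spec = DistributionSpec(family, rate=est.rate_hat, shape=est.shape_hat)
        assert est.median_hat == pytest.approx(median(refit_spec), rel=1e-9)


class TestBatchParity:
    """The vectorized Monte-Carlo path must match the scalar fitters."""

    @pytest.mark.parametrize("family", ["exponential", "weibull", "genexp"])
    def test_batch_equals_scalar(self, family):
        spec = DistributionSpec(
            family, rate=0.1, shape=1.0 if family == "exponential" else 2.0
        )
        u, d = simulate_matrix(spec, 6, 120, seed=21, censoring=0.2)
        batch = fit_batch(family, u, d)
        for i in range(6):
            est = fit(SurvivalSample(u[i], d[i].astype(int)), family)
            assert batch.median[i] == pytest.approx(est.median_hat, rel=2e-4)
            assert batch.se[i] == pytest.approx(est.se_median, rel=2e-3)

    def test_batch_flags_eventless_rows(self):
        u = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        d = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        batch = fit_batch("exponential", u, d)
        assert batch.ok.tolist() == [True, False]


class TestSamplingDistributions:
    @pytest.mark.parametrize(
        "family,shape,censoring,tol",
        [
            ("weibull", 2.0, 0.0, 0.05),
            ("weibull", 2.0, 0.3, 0.10),
            ("genexp", 2.0, 0.0, 0.05),
            ("genexp", 2.0, 0.3, 0.10),
        ],
    )
    def test_parameter_recovery_in_mean(self, family, shape, censoring, tol):
        """Mean of 200 fitted (shape, rate) pairs at n=500 near truth."""
        spec = DistributionSpec(family, rate=0.10, shape=shape)
        u, d = simulate_matrix(spec, 200, 500, seed=33, censoring=censoring)
        batch = fit_batch(family, u, d)
        assert batch.ok.mean() > 0.95
        assert abs(batch.shape[batch.ok].mean() - shape) / shape < tol
        assert abs(batch.rate[batch.ok].mean() - 0.10) / 0.10 < tol

    def test_log_rate_normal_approximation(self):
        """Var(ln theta_hat) ~ 1/(n p) for the exponential model."""
        spec = DistributionSpec("exponential", rate=0.1)
        u, d = simulate_matrix(spec, 2000, 200, seed=37)
        batch = fit_batch("exponential", u, d)
        v = np.var(np.log(batch.rate), ddof=1)
        assert abs(v - 1 / 200) / (1 / 200) < 0.15

    def test_se_scales_as_inverse_sqrt_n(self):
        """se * sqrt(n) stable across n = 200, 400, 800 (within 20%)."""
        spec = DistributionSpec("weibull", rate=0.10, shape=2.0)
        vals = []
        for n in (200, 400, 800):
            u, d = simulate_matrix(spec, 150, n, seed=41)
            batch = fit_batch("weibull", u, d)
            vals.append(batch.se[batch.ok].mean() * np.sqrt(n))
        assert (max(vals) - min(vals)) / min(vals) < 0.20
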