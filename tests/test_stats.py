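import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from antflow.diffusion_model import GasModelParams, simulate_gas, simulate_structured
from antflow.stats import (
    compare_models,
    correlation_test,
    csr_test,
    degree_window_transform,
    fit_binomial,
    fit_exponential,
    fit_pareto,
    sma_fit,
    specialization_tests,
    spike_cross_correlation,
    waiting_times,
)
from conftest import make_log


class TestSMA:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 10, 20)
        fit = sma_fit(x, 2 * x + 1, hypothesized_slope=2.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.p_value == 1.0  # test statistic exactly 0
        assert fit.ci[0] <= 2.0 <= fit.ci[1]

    def test_slope_is_sd_ratio(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 2.0, 200)
        y = rng.normal(0, 3.0, 200)  # independent: slope magnitude sd(y)/sd(x)
        fit = sma_fit(x, y)
        assert abs(fit.slope) == pytest.approx(np.std(y, ddof=1) / np.std(x, ddof=1))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = 1.4 * x + rng.normal(0, 0.3, 50)
        fit1 = sma_fit(x, y)
        fit2 = sma_fit(x, 5.0 * y)
        assert fit2.slope == pytest.approx(5.0 * fit1.slope)

    def test_negative_correlation_gives_negative_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        y = -2.0 * x + rng.normal(0, 0.1, 100)
        assert sma_fit(x, y).slope < 0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="x axis"):
            sma_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ci_coverage_near_nominal(self):
        # bivariate normal with true SMA slope 0.7 (sd(y)/sd(x) = 0.7)
        rng = np.random.default_rng(3)
        covered = 0
        n_reps = 400
        for _ in range(n_reps):
            x = rng.normal(0, 1.0, 500)
            e = rng.normal(0, 1.0, 500)
            y = 0.7 * (0.8 * x + 0.6 * e)  # sd(y)=0.7, corr=0.8
            fit = sma_fit(x, y)
            covered += fit.ci[0] <= 0.7 <= fit.ci[1]
        assert covered / n_reps >= 0.93

    def test_type_one_error_near_alpha(self):
        rng = np.random.default_rng(4)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            x = rng.normal(0, 1.0, 60)
            e = rng.normal(0, 1.0, 60)
            y = 1.3 * (0.6 * x + 0.8 * e)  # true SMA slope 1.3
            if sma_fit(x, y, hypothesized_slope=1.3).p_value < 0.05:
                rejections += 1
        rate = rejections / n_reps
        margin = 3 * math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= margin

    def test_correlation_test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 1, 40)
        r, p = correlation_test(x, y)
        r2, p2 = sps.pearsonr(x, y)
        assert (r, p) == (pytest.approx(r2), pytest.approx(p2))


class TestMLEFits:
    def test_exponential_reciprocal_mean(self):
        fit = fit_exponential([1.0, 1.0, 1.0])
        assert fit.rate == 1.0
        assert fit.loglik == pytest.approx(-3.0)

    def test_pareto_divergent_at_boundary(self):
        with pytest.raises(ValueError, match="diverges"):
            fit_pareto([2.0, 2.0, 2.0], xmin=2.0)

    def test_pareto_recovery(self):
        rng = np.random.default_rng(6)
        samples = 1.0 * (1 - rng.uniform(size=10_000)) ** (-1 / 1.5)  # alpha = 2.5
        fit = fit_pareto(samples, xmin=1.0)
        se = (fit.alpha - 1) / math.sqrt(fit.n)
        assert abs(fit.alpha - 2.5) <= 3 * se

    def test_binomial_mle(self):
        fit = fit_binomial([2, 3, 4, 3], trials=10)
        assert fit.p == pytest.approx(0.3)

    def test_mles_maximise_likelihood(self):
        # brute-force check: no nearby parameter beats the closed-form MLE
        rng = np.random.default_rng(7)
        x = rng.exponential(2.0, 50)
        fit = fit_exponential(x)
        grid = np.linspace(fit.rate * 0.5, fit.rate * 1.5, 201)
        loglik = x.size * np.log(grid) - grid * x.sum()
        assert fit.loglik >= loglik.max() - 1e-9

        y = 1.0 * (1 - rng.uniform(size=50)) ** (-1 / 1.2)
        pareto = fit_pareto(y, xmin=1.0)
        grid = np.linspace(1.01, pareto.alpha * 2, 400)
        s = np.sum(np.log(y / 1.0))
        loglik = y.size * np.log(grid - 1) - grid * s
        assert pareto.loglik >= loglik.max() - 1e-6


class TestCompareModels:
    def test_exponential_data_prefers_exponential(self):
        rng = np.random.default_rng(8)
        wins = 0
        for _ in range(100):
            x = rng.exponential(1.0, 1000)
            comparison = compare_models(x, ("exponential", "pareto"))
            wins += comparison.preferred == "exponential"
        assert wins >= 95

    def test_pareto_data_prefers_pareto_decisively(self):
        rng = np.random.default_rng(9)
        decisive = 0
        for _ in range(100):
            x = 1.0 * (1 - rng.uniform(size=1000)) ** (-1 / 0.8)  # alpha = 1.8
            comparison = compare_models(x, ("exponential", "pareto"), xmin=1.0)
            decisive += comparison.preferred == "pareto" and comparison.delta_aic > 10
        assert decisive >= 95

    def test_order_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.exponential(1.0, 300)
        a = compare_models(x, ("exponential", "pareto"))
        b = compare_models(x[::-1], ("exponential", "pareto"))
        assert a.aic == pytest.approx(b.aic)

    def test_inapplicable_candidate_excluded(self):
        x = np.concatenate([[-1.0], np.abs(np.random.default_rng(0).normal(1, 0.1, 50))])
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                compare_models(x, ("exponential", "pareto"))


class TestCSR:
    def test_uniform_positions_calibrated(self):
        rng = np.random.default_rng(11)
        passes = 0
        for _ in range(60):
            events = [
                (float(t), "A", "B", float(rng.uniform(0, 20)), float(rng.uniform(0, 20)))
                for t in np.sort(rng.uniform(0, 99, 500))
            ]
            result = csr_test(make_log(events, duration=100.0))
            passes += result.p_x > 0.01 and result.p_y > 0.01
        assert passes >= 54  # ~ (1 - 2 * 0.01) of 60

    def test_point_mass_rejected(self):
        events = [(float(t), "A", "B", 5.0, 5.0) for t in range(20)]
        result = csr_test(make_log(events, duration=30.0))
        assert result.p_x < 1e-6 and result.p_y < 1e-6

    def test_gas_contacts_near_uniform(self, gas_log):
        # contact positions have a ~D-wide wall depletion layer; at full-log n
        # the KS statistic stays small even where p-values reject
        result = csr_test(gas_log)
        assert result.ks_x < 0.08 and result.ks_y < 0.08


class TestSpikeTrains:
    def test_shifted_train_peaks_at_shift(self):
        k = 5  # bins
        events = []
        rng = np.random.default_rng(12)
        for t in np.sort(rng.uniform(0, 500, 60)):
            events.append((float(t), "X", "Y"))
            events.append((float(t) + k, "Z", "X"))
        log = make_log(events, duration=520.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = spike_cross_correlation(log, bin_width=1.0, max_lag=20)
        cc_x = result.per_individual["X"]
        assert result.lags[np.argmax(cc_x)] == k

    def test_independent_trains_nonsignificant(self):
        rng = np.random.default_rng(13)
        nonsig = 0
        for _ in range(25):
            events = []
            for t in np.sort(rng.uniform(0, 600, 80)):
                events.append((float(t), "X", "Y"))
            for t in np.sort(rng.uniform(0, 600, 80)):
                events.append((float(t), "Z", "X"))
            log = make_log(events, duration=620.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = spike_cross_correlation(log, max_lag=30)
            nonsig += result.p_value > 0.05
        assert nonsig >= 20

    def test_gas_log_shows_no_feedback(self, gas_log):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = spike_cross_correlation(gas_log, bin_width=1.0, max_lag=60)
        assert result.p_value > 0.05


class TestSpecialization:
    @staticmethod
    def _symmetric_log(rng, names, n_pairs, duration=200.0):
        events = []
        t = 1.0
        pairs = set()
        while len(pairs) < n_pairs:
            a, b = rng.choice(len(names), 2, replace=False)
            pairs.add((min(a, b), max(a, b)))
        for a, b in sorted(pairs):
            events.append((t, names[a], names[b]))
            events.append((t + 0.5, names[b], names[a]))
            t += 1.0
        return make_log(events, individuals=names, duration=duration)

    def test_symmetric_log_has_unit_within_slope(self):
        rng = np.random.default_rng(14)
        names = [f"W{k}" for k in range(10)]
        log1 = self._symmetric_log(rng, names, 18)
        log2 = self._symmetric_log(rng, names, 18)
        result = specialization_tests(log1, log2)
        for fit in result.within:
            assert fit.slope == pytest.approx(1.0)  # in-degree == out-degree
            assert fit.p_value == 1.0

    def test_gas_pair_shows_no_specialization(self):
        # homogeneous gas: no cross-recording coupling, and with fair-coin
        # role assignment the in/out streams are independent Poisson
        # thinnings, so the in-vs-out SMA slope magnitude is ~sd ratio = 1
        # while its sign/significance carries no information
        params = GasModelParams(m=30, width=20.0, height=20.0, v=1.0)
        log1 = simulate_gas(params, 300.0, rng_seed=20, record_positions=False)
        log2 = simulate_gas(params, 300.0, rng_seed=21, record_positions=False)
        result = specialization_tests(log1, log2)
        assert result.across_p > 0.01  # independent recordings: no coupling
        for fit in result.within:
            assert 0.7 <= abs(fit.slope) <= 1.4

    def test_heterogeneous_activity_couples_in_and_out_degree(self):
        # spatial fidelity creates persistent activity differences between
        # individuals; both degrees then scale with activity: slope ~ 1
        params = GasModelParams(m=30, width=20.0, height=20.0, v=1.0)
        log1 = simulate_structured(params, 900.0, 1.5, 0.25, rng_seed=30,
                                   record_positions=False)
        log2 = simulate_structured(params, 900.0, 1.5, 0.25, rng_seed=31,
                                   record_positions=False)
        result = specialization_tests(log1, log2)
        for fit in result.within:
            assert fit.r > 0
            assert fit.ci[0] <= 1.0 <= fit.ci[1]

    def test_too_few_shared_raises(self):
        log1 = make_log([(1.0, "A", "B")], duration=5.0)
        log2 = make_log([(1.0, "C", "D")], duration=5.0)
        with pytest.raises(ValueError):
            specialization_tests(log1, log2)


class TestWaitingTimes:
    def test_gaps_computed_per_individual(self):
        log = make_log(
            [(1.0, "A", "B"), (4.0, "A", "C"), (9.0, "B", "C")], duration=10.0
        )
        gaps = sorted(waiting_times(log))
        # A: 3 (1->4); B: 8 (1->9); C: 5 (4->9)
        assert gaps == [3.0, 5.0, 8.0]

    def test_degree_window_transform_drops_saturated(self):
        with pytest.warns(UserWarning, match="saturated"):
            out = degree_window_transform([0.0, 5.0, 9.0], m=10)
        assert out.size == 2
        assert out[0] == 0.0
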