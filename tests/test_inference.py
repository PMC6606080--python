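import numpy as np
import pytest
from scipy import stats

from histddm import (
    bf_correlation,
    combine_bf,
    corrected_p_repeat_at_lag,
    fit_exponential_kernel,
    markov_expected_repeat,
    p_repeat_at_lag,
    spearman,
    steiger_compare,
)
from conftest import make_trials


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x**3).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        # independent oracle: average ranks, then Pearson on the ranks
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).rho == pytest.approx(oracle, abs=1e-12)

    def test_ci_contains_rho(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        rep = spearman(x, x + rng.normal(size=30))
        assert rep.ci95[0] < rep.rho < rep.ci95[1]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])


class TestSteiger:
    def test_equal_correlations_null(self):
        z, p = steiger_compare(0.4, 0.4, 0.2, 50)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_swap_symmetry(self):
        z1, p1 = steiger_compare(0.5, 0.3, 0.2, 100)
        z2, p2 = steiger_compare(0.3, 0.5, 0.2, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            steiger_compare(1.0, 0.3, 0.2, 100)
        with pytest.raises(ValueError):
            steiger_compare(0.5, 0.3, 0.2, 3)

    def test_larger_sample_larger_z(self):
        z_small, _ = steiger_compare(0.5, 0.3, 0.2, 30)
        z_big, _ = steiger_compare(0.5, 0.3, 0.2, 300)
        assert abs(z_big) > abs(z_small)


class TestBayesFactor:
    def test_null_evidence_at_zero_correlation(self):
        assert bf_correlation(0.0, 200) < 1 / 10

    def test_strong_evidence_at_large_correlation(self):
        assert bf_correlation(0.9, 30) > 10

    def test_monotone_in_magnitude(self):
        bfs = [bf_correlation(r, 50) for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_combination_is_product(self):
        assert combine_bf([0.5, 0.2]) == pytest.approx(0.1)
        assert combine_bf([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert combine_bf([3.0, 0.5, 2.0]) == pytest.approx(combine_bf([2.0, 3.0, 0.5]))

    def test_empty_combination_rejected(self):
        with pytest.raises(ValueError):
            combine_bf([])


class TestExponentialKernel:
    def test_noiseless_recovery(self):
        lags = np.arange(1, 7)
        w = 1.0 * np.exp(-lags / 2.0)
        fit = fit_exponential_kernel(w, lags)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.tau == pytest.approx(2.0, abs=1e-6)
        assert not fit.at_bound

    def test_constant_weights_flag_boundary(self):
        fit = fit_exponential_kernel(np.full(6, 0.3))
        assert fit.at_bound

    def test_noisy_recovery_median_within_15_percent(self):
        rng = np.random.default_rng(3)
        lags = np.arange(1, 7)
        true = 1.0 * np.exp(-lags / 2.0)
        taus = []
        for _ in range(500):
            fit = fit_exponential_kernel(true + rng.normal(0, 0.05, size=6), lags)
            taus.append(fit.tau)
        assert abs(np.median(taus) - 2.0) / 2.0 < 0.15


class TestLaggedRepetition:
    def test_markov_expectation_values(self):
        assert markov_expected_repeat(0.5, 3) == pytest.approx(0.5)
        assert markov_expected_repeat(1.0, 5) == pytest.approx(1.0)
        assert markov_expected_repeat(0.7, 2) == pytest.approx(0.58)

    def test_corrected_value_uses_markov_baseline(self):
        t = make_trials([1, 1, 1, 1, 1, 1])
        r = corrected_p_repeat_at_lag(t, 2)
        assert r.raw == pytest.approx(1.0)
        assert r.expected == pytest.approx(1.0)
        assert r.corrected == pytest.approx(0.0)
        assert r.method == "markov_lag1_correction"

    def test_alternator_at_even_lag(self):
        t = make_trials([1, -1, 1, -1, 1, -1, 1, -1])
        assert p_repeat_at_lag(t, 2) == pytest.approx(1.0)
        r = corrected_p_repeat_at_lag(t, 2)
        assert r.expected == pytest.approx(1.0)  # (2*0-1)^2 -> 1

    def test_lag_below_two_rejected(self):
        with pytest.raises(ValueError):
            corrected_p_repeat_at_lag(make_trials([1, 1, 1]), 1)
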