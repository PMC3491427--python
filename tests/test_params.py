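"""Embedding-parameter estimation: FNN dimension, auto-MI delay, aggregation."""

import numpy as np
import pytest

from orpan.params import (
    aggregate_params,
    estimate_delay,
    estimate_dimension,
    fnn_fraction,
    mi_profile,
    mutual_information,
    realign_times,
)


def binned_entropy(u, n_bins):
    """Independent oracle: Shannon entropy (bits) of the binned marginal."""
    counts, _ = np.histogram(u, bins=n_bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


class TestMutualInformation:
    def test_zero_lag_equals_marginal_entropy(self, rng):
        u = rng.normal(size=2000)
        for n_bins in (8, 32, 100):
            assert mutual_information(u, 0, n_bins) == pytest.approx(
                binned_entropy(u, n_bins), abs=1e-10
            )

    def test_independent_samples_near_zero(self, rng):
        # i.i.d. noise: MI at any positive lag is pure estimator bias
        u = rng.normal(size=20000)
        assert mutual_information(u, 7, 10) < 0.02

    def test_sine_mi_minimum_near_quarter_period(self, rng):
        # period 200 samples -> the MI profile bottoms out near lag 50;
        # mild observational noise keeps the histogram non-degenerate
        t = np.arange(6000)
        u = np.sin(2 * np.pi * t / 200) + 0.05 * rng.normal(size=t.size)
        mi = mi_profile(u, 80, n_bins=16)
        # brute-force oracle: global minimum of the profile over lags 1..80
        lag_min = int(np.argmin(mi[1:]) + 1)
        assert 40 <= lag_min <= 60
        # the first local minimum can only stop at or before the global one
        assert 1 <= estimate_delay(u, 80, n_bins=16) <= lag_min

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert mutual_information(np.ones(100), 3, 10) == 0.0

    def test_bad_inputs(self, rng):
        u = rng.normal(size=50)
        with pytest.raises(ValueError):
            mutual_information(u, -1, 10)
        with pytest.raises(ValueError):
            mutual_information(u, 3, 1)
        with pytest.raises(ValueError):
            mutual_information(u, 50, 10)


class TestEstimateDelay:
    def test_lorenz_delay_in_mi_basin(self):
        # The auto-MI minimum of the benchmark's first component is a broad
        # basin around lag ~30; a longer realization pins the estimate there.
        from orpan.simulate import LorenzConfig, simulate_coupled_lorenz

        x, _ = simulate_coupled_lorenz(LorenzConfig(g=0.0, length=5000, seed=5))
        tau = estimate_delay(x, max_lag=60, n_bins=100)
        assert 25 <= tau <= 40

    def test_fallback_is_global_argmin_with_warning(self, rng):
        # strongly low-passed noise: auto-MI decays monotonically over a
        # short lag range, so no local minimum exists before max_lag
        kernel = np.ones(50) / 50
        u = np.convolve(rng.normal(size=30000), kernel, mode="valid")
        max_lag = 8
        mi = mi_profile(u, max_lag, n_bins=16)
        assert np.all(np.diff(mi[1:]) < 0), "precondition: strictly decreasing MI"
        with pytest.warns(UserWarning, match="global arg-min"):
            tau = estimate_delay(u, max_lag, n_bins=16)
        assert tau == max_lag

    def test_coarse_binning_inflates_delay(self, rng):
        # few bins flatten the MI profile and push its first minimum later
        from orpan.simulate import LorenzConfig, simulate_coupled_lorenz

        taus_10, taus_100 = [], []
        for seed in (11, 12, 13):
            x, y = simulate_coupled_lorenz(LorenzConfig(g=0.0, length=3000, seed=seed))
            for u in (x, y):
                taus_10.append(estimate_delay(u, 80, n_bins=10))
                taus_100.append(estimate_delay(u, 80, n_bins=100))
        assert np.mean(taus_10) > np.mean(taus_100)

    def test_max_lag_validation(self, rng):
        with pytest.raises(ValueError):
            estimate_delay(rng.normal(size=100), max_lag=1)


class TestFnnDimension:
    def test_white_noise_never_converges(self, rng):
        u = rng.normal(size=1000)
        d, converged = estimate_dimension(u, tau=1, max_d=8)
        assert d == 8 and not converged

    def test_white_noise_fraction_high_at_low_dimension(self, rng):
        # brute-force-checked regime: noise has no deterministic structure,
        # so low-dimensional embeddings are overwhelmingly false
        u = rng.normal(size=500)
        assert fnn_fraction(u, 1, 1) > 0.9
        assert fnn_fraction(u, 2, 1) > 0.4

    def test_dense_sine_resolves_at_two(self, rng):
        # tiny noise separates the otherwise exactly duplicated points of
        # successive periods, which would make the distance ratio degenerate
        t = np.arange(2000)
        u = np.sin(2 * np.pi * t / 100) + 0.01 * rng.normal(size=t.size)
        assert fnn_fraction(u, 2, 25) < 0.1
        d, converged = estimate_dimension(u, tau=25, max_d=6)
        assert converged and d == 2

    def test_lorenz_dimension_estimate(self, lorenz_uncoupled):
        x, _ = lorenz_uncoupled
        d, converged = estimate_dimension(x, tau=30, max_d=8)
        assert converged and d == 2

    def test_monotone_ramp_trivially_two(self):
        u = np.linspace(0, 1, 400)
        d, converged = estimate_dimension(u, tau=3, max_d=6)
        assert converged and d == 2

    def test_threshold_monotonicity(self, lorenz_uncoupled):
        # a looser threshold never yields a larger dimension
        x, _ = lorenz_uncoupled
        dims = [
            estimate_dimension(x, tau=30, max_d=8, threshold=thr)[0]
            for thr in (0.02, 0.05, 0.1, 0.3)
        ]
        assert all(a >= b for a, b in zip(dims, dims[1:]))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fnn_fraction(np.arange(20.0), d=4, tau=5)


class TestAggregation:
    def test_mode_and_rounded_mean(self):
        p = aggregate_params([2, 3, 3, 3], [14, 16])
        assert (p.d, p.tau, p.d_hat) == (3, 15, 8)

    def test_all_two_gives_over_embedded_six(self):
        p = aggregate_params([2, 2, 2], [30, 30, 30])
        assert (p.d, p.d_hat, p.tau) == (2, 6, 30)
        assert p.span == 150

    def test_single_channel_passthrough(self):
        p = aggregate_params([4], [7])
        assert (p.d, p.tau) == (4, 7)

    def test_mode_tie_broken_toward_smaller(self):
        assert aggregate_params([2, 2, 3, 3], [10]).d == 2

    def test_half_rounds_away_from_zero(self):
        assert aggregate_params([2], [14, 15]).tau == 15

    def test_permutation_invariance(self, rng):
        ds = list(rng.integers(2, 6, size=9))
        taus = list(rng.integers(5, 40, size=9))
        base = aggregate_params(ds, taus)
        for _ in range(5):
            perm_d = list(rng.permutation(ds))
            perm_t = list(rng.permutation(taus))
            shuffled = aggregate_params(perm_d, perm_t)
            assert (shuffled.d, shuffled.tau) == (base.d, base.tau)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_params([], [])


class TestRealignment:
    @pytest.mark.parametrize(
        "t, d_hat, tau, expected",
        [(0, 8, 15, 52.5), (100, 6, 30, 175.0), (7, 2, 1, 7.5)],
    )
    def test_window_centre(self, t, d_hat, tau, expected):
        assert realign_times(t, d_hat, tau) == expected

    def test_millisecond_conversion(self):
        # 1000 Hz: one sample = 1 ms
        assert realign_times(0, 8, 15, sampling_rate=1000.0) == 52.5
        # 500 Hz: one sample = 2 ms
        assert realign_times(0, 8, 15, sampling_rate=500.0) == 105.0

    def test_vectorized(self):
        out = realign_times(np.arange(3), 6, 30)
        np.testing.assert_allclose(out, [75.0, 76.0, 77.0])
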