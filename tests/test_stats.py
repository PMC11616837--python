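"""Descriptive statistics, gamma fitting, KDE, firing rate and Fano factor."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats as sps

import protospike as ps
from protospike.stats import _gamma_loglik


class TestSummarize:
    def test_rms_by_hand(self):
        s = ps.summarize([3.0, 4.0])
        assert s.rms == pytest.approx(np.sqrt(12.5), abs=1e-6)

    def test_peak_to_peak_is_max_minus_min(self, rng):
        x = rng.normal(5, 2, 100)
        s = ps.summarize(x)
        assert s.peak_to_peak == pytest.approx(s.max - s.min)

    def test_single_value_degenerate(self):
        s = ps.summarize([7.0])
        assert s.mean == s.min == s.max == 7.0
        assert s.sd == 0.0
        assert s.degenerate

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ps.summarize([])

    def test_permutation_invariant(self, rng):
        import dataclasses

        x = rng.exponential(1.0, 50)
        a = dataclasses.asdict(ps.summarize(x))
        b = dataclasses.asdict(ps.summarize(x[::-1].copy()))
        for key in a:  # summation order may differ in the last ulps
            assert a[key] == pytest.approx(b[key], rel=1e-9), key

    def test_quartile_ordering_always_holds(self, rng):
        for _ in range(20):
            s = ps.summarize(rng.standard_cauchy(rng.integers(2, 40)))
            assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


class TestMomentEstimators:
    def test_symmetric_sample_zero_skew(self):
        assert ps.skewness([-1.0, 0.0, 1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_plugin_skewness_by_hand(self):
        # (0,0,0,1): m3/m2^1.5 = 0.09375 / 0.1875^1.5
        assert ps.skewness([0, 0, 0, 1]) == pytest.approx(1.1547, abs=1e-4)

    def test_plugin_kurtosis_by_hand(self):
        assert ps.kurtosis([0, 0, 0, 1]) == pytest.approx(2.3333, abs=1e-4)

    def test_two_point_kurtosis_minimum(self):
        assert ps.kurtosis([-1, 1, -1, 1]) == pytest.approx(1.0)

    def test_gamma_skewness_large_sample(self, rng):
        # gamma(shape=4): skewness 2/sqrt(4) = 1
        x = rng.gamma(4.0, 1.0, 1_000_000)
        assert ps.skewness(x) == pytest.approx(1.0, abs=0.02)

    def test_normal_kurtosis_large_sample(self, rng):
        x = rng.standard_normal(1_000_000)
        assert ps.kurtosis(x) == pytest.approx(3.0, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ps.skewness([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            ps.kurtosis([2.0, 2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st_.lists(st_.floats(-50, 50), min_size=4, max_size=30),
        st_.floats(-100, 100),
        st_.floats(0.01, 100),
    )
    def test_location_scale_invariance(self, xs, shift, scale):
        x = np.asarray(xs)
        if np.var(x) < 1e-6:
            return
        base = ps.skewness(x)
        assert ps.skewness(x * scale + shift) == pytest.approx(base, abs=1e-6)
        assert ps.skewness(-x) == pytest.approx(-base, abs=1e-6)
        assert ps.kurtosis(x * scale + shift) == pytest.approx(
            ps.kurtosis(x), rel=1e-6
        )


class TestGammaPdf:
    def test_exponential_closed_form(self):
        assert ps.gamma_pdf(0.5, 1.0, 1.0) == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_shape_two_closed_form(self):
        assert ps.gamma_pdf(1.0, 2.0, 1.0) == pytest.approx(np.exp(-1.0), abs=1e-6)

    def test_mode_at_shape_minus_one_times_scale(self):
        shape, scale = 5.0, 2.0
        mode = (shape - 1) * scale
        x = np.linspace(0.1, 30, 2000)
        dens = ps.gamma_pdf(x, shape, scale)
        assert x[np.argmax(dens)] == pytest.approx(mode, abs=0.05)

    def test_domain_violations(self):
        with pytest.raises(ValueError):
            ps.gamma_pdf(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ps.gamma_pdf(1.0, -1.0, 1.0)


class TestGammaMLE:
    def test_parameter_recovery(self, rng):
        x = rng.gamma(32.27402, 0.01904, 100_000)
        fit = ps.fit_gamma_mle(x)
        assert fit.converged
        assert fit.shape == pytest.approx(32.27402, rel=0.02)

    def test_exponential_is_gamma_shape_one(self, rng):
        x = rng.exponential(1.0, 100_000)
        fit = ps.fit_gamma_mle(x)
        assert fit.shape == pytest.approx(1.0, rel=0.02)

    def test_first_moment_identity(self, rng):
        x = rng.gamma(3.0, 2.0, 500)
        fit = ps.fit_gamma_mle(x)
        assert fit.mean == pytest.approx(x.mean(), rel=1e-10)

    def test_loglik_beats_moment_start(self, rng):
        # the MLE must not be worse than the method-of-moments start
        x = rng.gamma(5.0, 0.3, 400)
        fit = ps.fit_gamma_mle(x)
        a_mom = x.mean() ** 2 / x.var(ddof=1)
        ll_mom = _gamma_loglik(x, a_mom, x.mean() / a_mom)
        assert fit.log_likelihood >= ll_mom - 1e-9

    def test_matches_scipy_fixed_loc_fit(self, rng):
        # independent route: scipy's gamma MLE with loc pinned at 0
        x = rng.gamma(2.5, 1.7, 5_000)
        fit = ps.fit_gamma_mle(x)
        a_sp, _, scale_sp = sps.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(a_sp, rel=1e-4)
        assert fit.scale == pytest.approx(scale_sp, rel=1e-4)

    def test_rejects_bad_input(self, rng):
        with pytest.raises(ValueError):
            ps.fit_gamma_mle([1.0] * 5)  # too few
        with pytest.raises(ValueError):
            ps.fit_gamma_mle([1.0] * 9 + [-1.0])


class TestKDE:
    def test_scott_bandwidth_formula(self, rng):
        # independent arithmetic from the sample's own sd and IQR
        x = rng.standard_normal(100)
        q1, q3 = np.percentile(x, [25, 75])
        expected = 100 ** (-0.2) * 1.06 * min(x.std(ddof=1), (q3 - q1) / 1.34)
        assert ps.scott_bandwidth(x) == pytest.approx(expected, rel=1e-12)
        # the worked reference: n=100, sd=1, IQR=1.349 -> h = 0.42200
        assert 100 ** (-0.2) * 1.06 * min(1.0, 1.349 / 1.34) == pytest.approx(
            0.42200, abs=5e-5
        )

    def test_scott_scale_equivariance(self, rng):
        x = rng.gamma(3, 1, 200)
        assert ps.scott_bandwidth(3.5 * x) == pytest.approx(
            3.5 * ps.scott_bandwidth(x), rel=1e-12
        )

    def test_scott_decreases_with_n(self, rng):
        x = rng.standard_normal(10_000)
        hs = [ps.scott_bandwidth(x[:n]) for n in (100, 1000, 10_000)]
        assert hs[0] > hs[1] > hs[2]

    def test_single_kernel_closed_form(self):
        est = ps.kde([0.0], bandwidth=1.0, grid=[0.0])
        assert est.density[0] == pytest.approx(1 / np.sqrt(2 * np.pi), abs=1e-6)

    def test_normalization(self, rng):
        x = rng.normal(2.0, 0.5, 300)
        h = ps.scott_bandwidth(x)
        grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, 800)
        est = ps.kde(x, h, grid)
        assert est.integral() == pytest.approx(1.0, abs=0.01)

    def test_bimodal_sample_two_modes(self, rng):
        x = np.concatenate([rng.normal(-3, 0.3, 200), rng.normal(3, 0.3, 200)])
        grid = np.linspace(-6, 6, 500)
        est = ps.kde(x, 0.3, grid)
        d = est.density
        interior_max = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
        assert interior_max.sum() == 2

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ps.kde([1.0], 0.0, [0.0])
        with pytest.raises(ValueError):
            ps.kde([1.0], 1.0, [])
        with pytest.raises(ValueError):
            ps.scott_bandwidth([2.0, 2.0])


class TestRateAndFano:
    def test_firing_rate_arithmetic(self):
        train = ps.SpikeTrain(
            spike_times=np.linspace(10, 990, 10),
            amplitudes=np.ones(10),
            duration=1000.0,
        )
        assert ps.firing_rate(train) == pytest.approx(0.01)

    def test_empty_train_rate_zero(self):
        train = ps.SpikeTrain(
            spike_times=np.empty(0), amplitudes=np.empty(0), duration=100.0
        )
        assert ps.firing_rate(train) == 0.0

    def test_periodic_rate_approaches_inverse_period(self):
        train = ps.generate_spike_train(ps.periodic(10.0), 1, 1, 10_000.0, 0)
        assert ps.firing_rate(train) == pytest.approx(0.1, rel=0.01)

    def test_poisson_fano_near_one(self):
        train = ps.generate_spike_train(
            ps.gamma_renewal(1.0, 10.0), 1, 1, 10_000.0, seed=11
        )
        assert ps.fano_factor(train, 1.0) == pytest.approx(1.0, abs=0.05)

    def test_periodic_fano_zero_at_multiple_of_period(self):
        train = ps.generate_spike_train(ps.periodic(5.0), 1, 1, 10_000.0, 0)
        assert ps.fano_factor(train, 50.0) == pytest.approx(0.0, abs=1e-2)

    def test_gamma_renewal_large_window_asymptote(self):
        train = ps.generate_spike_train(
            ps.gamma_renewal(2.0, 2.0), 1, 1, 50_000.0, seed=5
        )
        assert ps.fano_factor(train, 100.0) == pytest.approx(0.5, abs=0.05)

    def test_too_few_windows_rejected(self):
        train = ps.SpikeTrain(spike_times=[1.0], amplitudes=[1.0], duration=10.0)
        with pytest.raises(ValueError):
            ps.fano_factor(train, 8.0)

    def test_zero_mean_count_undefined(self):
        train = ps.SpikeTrain(
            spike_times=np.empty(0), amplitudes=np.empty(0), duration=100.0
        )
        assert ps.fano_factor(train, 10.0) is None

    def test_cv_of_gamma_isis(self):
        train = ps.generate_spike_train(
            ps.gamma_renewal(2.0, 1.0), 1, 1, 200_000.0, seed=2
        )
        assert ps.cv_isi(train) == pytest.approx(1 / np.sqrt(2), rel=0.01)
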