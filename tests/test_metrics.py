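"""Analysis-suite operations against analytic and constructed oracles."""

import numpy as np
import pytest

from protact import (LogisticParams, LyapunovConfig, VoltageTrace,
                     cross_correlate, generate_logistic, lyapunov_wolf,
                     pca_input_output, peaks_per_second, smooth_savgol,
                     spectrum, summarize)
from protact.metrics import LyapunovEstimationError, MetricsError
from conftest import make_trace


class TestSummarize:
    def test_constant_trace(self, constant_trace):
        s = summarize(constant_trace)
        assert s.mean == s.median == s.max == s.min == 0.3
        assert s.sd == 0.0 and s.dominant_freq == 0.0

    def test_sine_dominant_frequency(self, sine_trace):
        s = summarize(sine_trace)
        assert abs(s.dominant_freq - 5.0) < 0.1
        assert abs(s.mean) < 1e-3 and abs(s.max - 1.0) < 1e-3

    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        tr = make_trace(rng.normal(size=1000))
        a, b = -2.5, 0.7
        s0 = summarize(tr)
        s1 = summarize(tr.with_values(a * tr.v + b))
        assert np.isclose(s1.mean, a * s0.mean + b)
        assert np.isclose(s1.median, a * s0.median + b)
        assert np.isclose(s1.sd, abs(a) * s0.sd)
        assert np.isclose(s1.max, a * s0.min + b)  # a < 0 flips extrema
        assert np.isclose(s1.min, a * s0.max + b)

    def test_time_translation_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=500)
        s0 = summarize(VoltageTrace.from_samples(v, dt=0.01, t0=0.0))
        s1 = summarize(VoltageTrace.from_samples(v, dt=0.01, t0=123.0))
        assert s0 == s1


class TestPeaksPerSecond:
    def test_three_hz_sine(self):
        dt = 1e-3
        t = np.arange(0, 10, dt)
        tr = VoltageTrace(t=t, v=np.sin(2 * np.pi * 3 * t), dt=dt)
        assert abs(peaks_per_second(tr) - 3.0) < 0.05

    def test_monotone_ramp_has_no_peaks(self):
        tr = make_trace(np.linspace(0, 1, 500))
        assert peaks_per_second(tr) == 0.0

    def test_noisy_square_wave(self):
        # 2 Hz square wave + 1% noise: prominence filter keeps 2.0 Hz
        dt = 1e-3
        t = np.arange(0, 10, dt)
        rng = np.random.default_rng(0)
        v = np.sign(np.sin(2 * np.pi * 2 * t)) + rng.normal(0, 0.01, len(t))
        assert abs(peaks_per_second(VoltageTrace(t=t, v=v, dt=dt)) - 2.0) < 0.11

    def test_zero_variance_returns_zero(self, constant_trace):
        assert peaks_per_second(constant_trace) == 0.0


class TestSpectrum:
    def test_dc_only_trace_peaks_at_zero(self, constant_trace):
        assert spectrum(constant_trace).dominant_mode == 0.0

    def test_sine_tone_dominates_by_20db(self, sine_trace):
        sp = spectrum(sine_trace)
        assert sp.dominant_mode == pytest.approx(5.0, abs=0.11)
        peak_bin = int(np.argmax(sp.power_db))
        others = np.delete(sp.power_db, peak_bin)
        assert sp.power_db[peak_bin] - others.max() >= 20.0

    def test_floor_is_applied(self, constant_trace):
        sp = spectrum(constant_trace)
        assert np.all(np.isfinite(sp.power_db))
        assert sp.power_db.min() >= -200.0


class TestCrossCorrelate:
    def test_self_pair_unit_at_zero_lag(self):
        rng = np.random.default_rng(1)
        tr = make_trace(rng.normal(size=2000))
        r = cross_correlate(tr, tr, max_lag=50)
        assert r.max_coeff == pytest.approx(1.0, abs=1e-12)
        assert r.argmax_lag == 0

    @pytest.mark.parametrize("k", [3, 17])
    def test_recovers_planted_delay(self, k):
        rng = np.random.default_rng(2)
        v = rng.normal(size=3000)
        a = make_trace(v)
        b = make_trace(np.roll(v, k))  # b trails a by k samples
        r = cross_correlate(a, b, max_lag=50)
        assert r.argmax_lag == k

    def test_zero_variance_rejected(self, constant_trace):
        with pytest.raises(MetricsError):
            cross_correlate(constant_trace, constant_trace, max_lag=5)

    def test_coefficients_bounded(self):
        rng = np.random.default_rng(5)
        a = make_trace(rng.normal(size=1000))
        b = make_trace(rng.normal(size=1000))
        r = cross_correlate(a, b, max_lag=100)
        assert np.all(np.abs(r.coeffs) <= 1.0 + 1e-12)


class TestPCA:
    def test_identical_pair_is_rank_one(self):
        rng = np.random.default_rng(6)
        tr = make_trace(rng.normal(size=500))
        p = pca_input_output(tr, tr)
        np.testing.assert_allclose(p.var_fraction, [1.0, 0.0], atol=1e-12)

    def test_isotropic_limit(self):
        rng = np.random.default_rng(7)
        a = make_trace(rng.normal(size=10_000))
        b = make_trace(rng.normal(size=10_000))
        p = pca_input_output(a, b, standardize=True)
        np.testing.assert_allclose(p.var_fraction, [0.5, 0.5], atol=0.02)

    def test_anticollinear_pair(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=2000)
        a = make_trace(v)
        b = make_trace(-v + rng.normal(0, 0.01, len(v)))
        p = pca_input_output(a, b)
        assert p.var_fraction[0] > 0.99

    def test_fractions_sum_to_one_and_swap_invariant(self):
        rng = np.random.default_rng(9)
        a = make_trace(rng.normal(size=800))
        b = make_trace(0.3 * a.v + rng.normal(0, 0.5, 800))
        p_ab = pca_input_output(a, b)
        p_ba = pca_input_output(b, a)
        assert abs(p_ab.var_fraction.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(p_ab.var_fraction, p_ba.var_fraction,
                                   atol=1e-12)

    def test_matches_closed_form_eigendecomposition(self):
        # independent oracle: eigenvalues of the 2x2 covariance matrix
        rng = np.random.default_rng(10)
        a = make_trace(rng.normal(size=3000))
        b = make_trace(0.6 * a.v + rng.normal(0, 0.4, 3000))
        p = pca_input_output(a, b)
        cov = np.cov(np.vstack([a.v, b.v]))
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(p.var_fraction, eig / eig.sum(),
                                   atol=1e-9)

    def test_degenerate_channel_flagged(self, constant_trace):
        rng = np.random.default_rng(11)
        b = constant_trace.with_values(rng.normal(size=len(constant_trace)))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            p = pca_input_output(constant_trace, b)
        assert p.degenerate
        np.testing.assert_allclose(p.var_fraction, [1.0, 0.0])


class TestSavgol:
    def test_reproduces_quadratic_exactly(self):
        t = np.arange(200) * 0.01
        v = 3.0 - 2.0 * t + 0.5 * t ** 2
        tr = VoltageTrace(t=t, v=v, dt=0.01)
        out = smooth_savgol(tr, order=2, frame=15)
        interior = slice(7, -7)
        np.testing.assert_allclose(out.v[interior], v[interior], atol=1e-10)

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(12)
        tr = make_trace(rng.normal(size=5000))
        assert smooth_savgol(tr).v.std() < tr.v.std()

    def test_impulse_response_matches_normal_equations_kernel(self):
        # closed-form kernel: first row of (A^T A)^{-1} A^T evaluated at
        # the window center, A the Vandermonde of offsets -7..7, order 2
        offsets = np.arange(-7, 8)
        A = np.vander(offsets, 3, increasing=True)
        kernel = (np.linalg.inv(A.T @ A) @ A.T)[0]
        impulse = np.zeros(31)
        impulse[15] = 1.0
        out = smooth_savgol(make_trace(impulse), order=2, frame=15)
        np.testing.assert_allclose(out.v[8:23], kernel[::-1], atol=1e-12)

    def test_invalid_frame_rejected(self, sine_trace):
        with pytest.raises(MetricsError):
            smooth_savgol(sine_trace, order=2, frame=14)
        with pytest.raises(MetricsError):
            smooth_savgol(sine_trace, order=5, frame=5)


class TestLyapunov:
    def test_constant_trace_has_no_pairs(self, constant_trace):
        with pytest.raises(LyapunovEstimationError):
            lyapunov_wolf(constant_trace)

    def test_mu4_logistic_near_ln2(self):
        tr = generate_logistic(LogisticParams(mu=4.0, seed=0, v_lo=0.0,
                                              v_hi=1.0))
        est = lyapunov_wolf(tr)
        assert abs(est.lambda_per_step - np.log(2)) / np.log(2) < 0.15
        assert est.n_pairs >= 1

    def test_decaying_exponential_is_negative(self):
        t = np.arange(0, 10, 1e-3)
        tr = VoltageTrace(t=t, v=np.exp(-t), dt=1e-3)
        assert lyapunov_wolf(tr).lambda_per_step < 0

    def test_sign_battery_over_20_seeds(self):
        # chaos positive, contraction negative, for every seed
        for seed in range(20):
            tr = generate_logistic(LogisticParams(mu=4.0, seed=seed,
                                                  v_lo=0.0, v_hi=1.0))
            assert lyapunov_wolf(tr).lambda_per_step > 0
        t = np.arange(0, 20, 2e-3)
        for phase in np.linspace(0, 1, 20):
            tr = VoltageTrace(t=t, v=np.exp(-(t + phase)), dt=2e-3)
            assert lyapunov_wolf(tr).lambda_per_step < 0

    def test_fixed_offset_mode_is_null_on_bounded_chaos(self):
        # the literal fixed-offset pairing rule averages to ~0 on a
        # measure-preserving series — the documented contrast to Wolf mode
        tr = generate_logistic(LogisticParams(mu=4.0, seed=1, v_lo=0.0,
                                              v_hi=1.0))
        est = lyapunov_wolf(tr, LyapunovConfig(mode="fixed_offset"))
        assert abs(est.lambda_per_step) < 0.05

    def test_presmoothing_runs(self):
        tr = generate_logistic(LogisticParams(mu=3.8, seed=2))
        est = lyapunov_wolf(tr, LyapunovConfig(presmooth=True))
        assert np.isfinite(est.lambda_per_step)

    def test_too_short_trace_rejected(self):
        tr = make_trace(np.arange(10.0))
        with pytest.raises(LyapunovEstimationError):
            lyapunov_wolf(tr)
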