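"""Drive generators against hand-iterated and closed-form oracles."""

import numpy as np
import pytest

from protact import (BakerParams, FHNParams, LogisticParams, LorenzParams,
                     PulseTrainParams, RosslerParams, generate_baker,
                     generate_fhn, generate_logistic, generate_lorenz,
                     generate_pulse_train, generate_rossler, rk4_integrate)
from protact.drives import DriveDomainError, baker_step


def logistic_oracle(mu, x0, n):
    """Direct hand iteration of x(n+1) = mu x (1 - x)."""
    xs = [x0]
    for _ in range(n - 1):
        xs.append(mu * xs[-1] * (1 - xs[-1]))
    return np.array(xs)


class TestLogistic:
    def test_matches_hand_iteration_mu4(self):
        p = LogisticParams(mu=4.0, x0=0.2, n_iter=10, v_lo=0.0, v_hi=1.0)
        tr = generate_logistic(p)
        np.testing.assert_allclose(tr.v, logistic_oracle(4.0, 0.2, 10),
                                   atol=1e-12)

    def test_fixed_point_gives_constant_trace(self):
        # x* = 1 - 1/mu is invariant; at mu=3.8 it is unstable
        # (|f'(x*)| = 1.8), so the 1-ulp representation error grows by
        # 1.8^n and the orbit visibly escapes only after ~60 iterates.
        x_star = 1 - 1 / 3.8
        tr = generate_logistic(LogisticParams(mu=3.8, x0=x_star, n_iter=25))
        assert np.ptp(tr.v) < 1e-8
        # at mu=2 the fixed point 0.5 is exactly representable and stable:
        tr2 = generate_logistic(LogisticParams(mu=2.0, x0=0.5, n_iter=10_000))
        assert np.ptp(tr2.v) == 0.0

    def test_voltage_scaling_and_length(self):
        tr = generate_logistic(LogisticParams(seed=7))
        assert len(tr) == 10_000
        assert tr.v.min() >= -0.5 and tr.v.max() <= 0.5

    def test_chaotic_orbit_spans_unit_interval(self):
        # mu=3.8 fully developed chaos covers most of [0,1] -> [-0.5, 0.5]
        tr = generate_logistic(LogisticParams(seed=1))
        assert tr.v.max() - tr.v.min() > 0.7

    @pytest.mark.parametrize("bad", [dict(x0=0.0), dict(x0=1.0),
                                     dict(mu=4.5), dict(mu=0.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(DriveDomainError):
            LogisticParams(seed=0, **bad)

    def test_iterates_stay_in_unit_interval(self):
        # invariant for mu <= 4, x0 in (0,1), over the full 10k-step run
        for mu in (3.5, 3.8, 4.0):
            tr = generate_logistic(LogisticParams(mu=mu, seed=11,
                                                  v_lo=0.0, v_hi=1.0))
            assert np.all((tr.v >= 0.0) & (tr.v <= 1.0))


def baker_oracle(alpha, x0, y0, n):
    pts = [(x0, y0)]
    for _ in range(n - 1):
        x, y = pts[-1]
        if x < alpha:
            pts.append((x / alpha, alpha * y))
        else:
            pts.append(((x - alpha) / (1 - alpha), alpha + (1 - alpha) * y))
    return np.array(pts)


class TestBaker:
    def test_matches_hand_iteration(self):
        pts = baker_oracle(0.5, 0.3, 0.4, 10)
        for comp, col in (("x", 0), ("y", 1)):
            tr = generate_baker(BakerParams(alpha=0.5, x0=0.3, y0=0.4,
                                            n_iter=10, v_lo=0.0, v_hi=1.0,
                                            component=comp))
            np.testing.assert_allclose(tr.v, pts[:, col], atol=1e-12)

    def test_origin_is_fixed_point(self):
        tr = generate_baker(BakerParams(x0=0.0, y0=0.0, n_iter=50))
        np.testing.assert_allclose(tr.v, -0.5, atol=1e-15)

    def test_emitted_range_is_bounded(self):
        tr = generate_baker(BakerParams(alpha=0.3, x0=0.71, y0=0.27,
                                        n_iter=5000, v_lo=-2.0, v_hi=3.0))
        assert tr.v.min() >= -2.0 and tr.v.max() <= 3.0

    def test_outside_unit_square_rejected(self):
        with pytest.raises(DriveDomainError):
            BakerParams(x0=1.2, y0=0.5)

    def test_map_is_area_preserving_on_jacobian(self):
        # both branches have unit Jacobian: |d x'/dx * d y'/dy| == 1
        for alpha in (0.3, 0.5, 0.8):
            assert np.isclose((1 / alpha) * alpha, 1.0)
            assert np.isclose((1 / (1 - alpha)) * (1 - alpha), 1.0)
            # and the map keeps the square invariant
            for pt in [(0.1, 0.9), (0.9, 0.1), (alpha, 0.5)]:
                x, y = baker_step(*pt, alpha)
                assert 0 <= x <= 1 and 0 <= y <= 1


class TestRK4:
    def test_reproduces_exponential_decay(self):
        # dx/dt = -x, closed form e^{-t}; RK4 at dt=0.01 is O(dt^4)
        traj = rk4_integrate(lambda t, y: -y, [1.0], 0.01, 100)
        t = 0.01 * np.arange(101)
        rel = np.abs(traj[:, 0] - np.exp(-t)) / np.exp(-t)
        assert rel.max() < 1e-8

    def test_nonfinite_state_names_step(self):
        from protact.drives import IntegrationError
        with np.errstate(over="ignore"), \
                pytest.raises(IntegrationError, match=r"step \d+"):
            rk4_integrate(lambda t, y: y ** 3, [10.0], 0.5, 100)


class TestLorenz:
    def test_default_run_shape_and_boundedness(self):
        tr = generate_lorenz(LorenzParams())
        assert len(tr) == 10_001
        assert np.max(np.abs(tr.v)) < 25.0  # attractor confinement

    def test_zero_coupling_freezes_x(self):
        p = LorenzParams(sigma=0.0, y0=(2.0, 2.0, 0.0), duration=1.0)
        tr = generate_lorenz(p)
        np.testing.assert_allclose(tr.v, 2.0, atol=1e-12)

    def test_against_fine_step_oracle(self):
        coarse = generate_lorenz(LorenzParams(duration=10.0))
        fine = generate_lorenz(LorenzParams(duration=10.0, dt=0.001))
        assert np.max(np.abs(coarse.v - fine.v[::10])) < 1e-2


class TestRossler:
    def test_origin_equilibrium_with_zero_b(self):
        p = RosslerParams(b=0.0, y0=(0.0, 0.0, 0.0), duration=1.0)
        tr = generate_rossler(p)
        np.testing.assert_allclose(tr.v, 0.0, atol=1e-15)

    def test_chaotic_run_has_positive_amplitude(self):
        tr = generate_rossler(RosslerParams())
        assert np.ptp(tr.v) > 1.0

    def test_against_fine_step_oracle(self):
        coarse = generate_rossler(RosslerParams(duration=10.0))
        fine = generate_rossler(RosslerParams(duration=10.0, dt=0.001))
        assert np.max(np.abs(coarse.v - fine.v[::10])) < 1e-2


class TestFHN:
    def test_subthreshold_drive_settles_to_quiescence(self):
        v, w = generate_fhn(FHNParams(c=1.0, duration=300.0))
        late = v.v[-5000:]
        assert np.ptp(late) < 1e-3

    def test_suprathreshold_drive_sustains_limit_cycle(self):
        v, w = generate_fhn(FHNParams(c=2.0, duration=300.0))
        late = v.v[-5000:]
        assert np.ptp(late) > 1.0

    def test_limit_cycle_period_converges_with_step(self):
        from scipy.signal import find_peaks

        def period(dt):
            v, _ = generate_fhn(FHNParams(c=2.0, duration=300.0, dt=dt))
            sig = v.v[int(100.0 / dt):]
            peaks, _ = find_peaks(sig, prominence=0.5)
            return np.diff(peaks).mean() * dt

        p_coarse, p_fine = period(0.01), period(0.001)
        assert abs(p_coarse - p_fine) / p_fine < 0.01


class TestPulseTrain:
    def test_seeded_runs_are_identical(self):
        p = PulseTrainParams(n_bits=10, seed=42)
        b1, t1 = generate_pulse_train(p)
        b2, t2 = generate_pulse_train(p)
        np.testing.assert_array_equal(b1.bits, b2.bits)
        np.testing.assert_array_equal(t1.v, t2.v)

    def test_encoding_of_known_bits(self):
        # 100 ms pulses at 100 ms bit spacing encode [1,0,1] as +/-0.5 V
        p = PulseTrainParams(n_bits=3, bit_dt=0.1, pulse_width=0.1, seed=0)
        found = None
        for seed in range(200):
            bits, tr = generate_pulse_train(
                PulseTrainParams(n_bits=3, bit_dt=0.1, pulse_width=0.1,
                                 seed=seed))
            if list(bits.bits) == [1, 0, 1]:
                found = tr
                break
        assert found is not None
        np.testing.assert_allclose(found.v, [0.5, -0.5, 0.5])

    def test_levels_follow_bits_without_overlap(self):
        # pulse_width == bit_dt: each sample is exactly its bit's level
        for seed in (0, 1, 2):
            bits, tr = generate_pulse_train(
                PulseTrainParams(n_bits=50, bit_dt=0.1, pulse_width=0.1,
                                 seed=seed))
            expected = np.where(bits.bits == 1, 0.5, -0.5)
            np.testing.assert_allclose(tr.v, expected)

    def test_determinism_across_generator_families(self):
        # all generators are pure functions of (params, seed)
        pairs = [
            (generate_logistic(LogisticParams(seed=3)),
             generate_logistic(LogisticParams(seed=3))),
            (generate_baker(BakerParams(x0=0.21, y0=0.73, n_iter=500)),
             generate_baker(BakerParams(x0=0.21, y0=0.73, n_iter=500))),
            (generate_lorenz(LorenzParams(duration=2.0)),
             generate_lorenz(LorenzParams(duration=2.0))),
        ]
        for a, b in pairs:
            np.testing.assert_array_equal(a.v, b.v)
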