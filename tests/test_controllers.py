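"""Controllers: setpoint logging, APqr adaptation, PID core and routing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optoclamp import (ApqrGains, ControllerState, LEState, Phase, PidGains,
                       SetpointAP, apqr_tick, le_tick, log_setpoint,
                       named_triangular, pid_tick, regress_slope,
                       route_output)
from optoclamp.controllers import revert_integral


def correcting_state(**kw):
    return ControllerState(phase=Phase.CORRECTING, **kw)


FLAT = SetpointAP(values=np.full(100, -70.0), origin="generator")


class TestLogSetpoint:
    def test_identical_beats_reproduce_the_beat(self):
        beat = np.linspace(-75, 20, 50)
        sp = log_setpoint([beat, beat], lognum=2)
        assert np.array_equal(sp.values, beat)
        assert sp.origin == "logged"

    def test_two_beat_mean(self):
        sp = log_setpoint([[0.0, 10.0], [2.0, 12.0]], lognum=2)
        assert sp.values.tolist() == [1.0, 11.0]

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        beats = [rng.normal(-40, 30, 200) for _ in range(5)]
        sp = log_setpoint(beats, lognum=5)
        brute = np.array([sum(b[i] for b in beats) / 5 for i in range(200)])
        np.testing.assert_allclose(sp.values, brute, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        beats = [rng.normal(size=64) for _ in range(4)]
        a = log_setpoint(beats, lognum=4).values
        b = log_setpoint(beats[::-1], lognum=4).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_count_and_length_validation(self):
        with pytest.raises(ValueError):
            log_setpoint([[1.0, 2.0]], lognum=2)
        with pytest.raises(ValueError):
            log_setpoint([[1.0, 2.0], [1.0, 2.0, 3.0]], lognum=2)


class TestApqr:
    def test_zero_error_zero_output_rm_unchanged(self):
        st_ = correcting_state()
        out, st_ = apqr_tick(-70.0, st_, FLAT, ApqrGains())
        assert out == 0.0
        assert st_.R_m_current == ApqrGains().R_m

    def test_proportional_arithmetic(self):
        g = ApqrGains(C_m=100.0, R_m=100.0)
        out, _ = apqr_tick(-65.0, correcting_state(), FLAT, g)
        assert out == pytest.approx(5.0)   # K_P = C_m/R_m = 1, e = 5

    def test_moving_away_doubles_gain_with_corr_down_2(self):
        g = ApqrGains(C_m=100.0, R_m=100.0, R_m_corr_down=2.0, R_m_min=1.0)
        st_ = correcting_state()
        out1, st_ = apqr_tick(-69.0, st_, FLAT, g)          # e=1, first tick
        out2, st_ = apqr_tick(-68.0, st_, FLAT, g)          # e=2 > 1, same sign
        out3, st_ = apqr_tick(-68.0, st_, FLAT, g)          # K_P now doubled
        assert out3 == pytest.approx(2.0 * out2)

    def test_overshoot_never_increases_gain(self):
        g = ApqrGains(R_m_min=1.0)
        st_ = correcting_state()
        _, st_ = apqr_tick(-69.0, st_, FLAT, g)
        rm_before = st_.R_m_current
        _, st_ = apqr_tick(-71.0, st_, FLAT, g)             # sign flip
        assert st_.R_m_current >= rm_before

    def test_moving_away_never_decreases_gain(self):
        g = ApqrGains(R_m_min=1.0)
        st_ = correcting_state()
        _, st_ = apqr_tick(-69.0, st_, FLAT, g)
        rm_before = st_.R_m_current
        _, st_ = apqr_tick(-67.0, st_, FLAT, g)             # |e| grew, same sign
        assert st_.R_m_current <= rm_before                  # K_P = C/R grew

    def test_requires_correcting_phase(self):
        with pytest.raises(ValueError):
            apqr_tick(-70.0, ControllerState(), FLAT, ApqrGains())


class TestRegressSlope:
    def test_constant_window_is_flat(self):
        assert regress_slope([4.2] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovers_slope_with_rising_sign(self):
        window = [3.0 * j for j in range(10)]   # error rising in time
        assert regress_slope(window, dt=1.0) == pytest.approx(3.0)

    def test_matches_polyfit_on_random_windows(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            l = int(rng.integers(2, 15))
            w = rng.normal(0, 20, l)
            expected = np.polyfit(np.arange(l) * 1.0, w, 1)[0]
            assert regress_slope(w, dt=1.0) == pytest.approx(expected,
                                                             abs=1e-9)

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            regress_slope([1.0])


class TestPid:
    def test_pure_proportional(self):
        g = PidGains(K_P=1.0, K_I=0.0, K_D=0.0)
        pid, _ = pid_tick(-67.0, correcting_state(), FLAT, g)
        assert pid == pytest.approx(3.0)

    def test_all_gains_zero(self):
        g = PidGains(K_P=0.0, K_I=0.0, K_D=0.0)
        st_ = correcting_state()
        for v in (-50.0, -90.0, 0.0, -70.0):
            pid, st_ = pid_tick(v, st_, FLAT, g)
            assert pid == 0.0

    def test_derivative_warm_up_is_zero(self):
        g = PidGains(K_P=0.0, K_I=0.0, K_D=10.0, l=5)
        st_ = correcting_state()
        for k in range(4):                      # fewer than l samples
            pid, st_ = pid_tick(-70.0 + k, st_, FLAT, g)
            assert pid == 0.0

    def test_trace_matches_step_by_step_oracle(self):
        """50-tick scripted V_m sequence against a literal re-evaluation."""
        g = PidGains(K_P=2.0, K_I=0.5, K_D=1.5, l=10)
        rng = np.random.default_rng(42)
        vms = (-70.0 + rng.normal(0, 8, 50)).tolist()
        st_ = correcting_state()
        got = [pid_tick(v, st_, FLAT, g)[0] for v in vms]

        e_sum, window, expect = 0.0, [], []
        for v in vms:
            e = v - (-70.0)
            e_sum += e
            window.append(e)
            window = window[-g.l:]
            if len(window) == g.l:
                der = np.polyfit(np.arange(g.l) * g.dt, window, 1)[0]
            else:
                der = 0.0
            expect.append(g.K_P * e + g.K_I * e_sum + g.K_D * der)
        np.testing.assert_allclose(got, expect, atol=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.1, 10.0), st.integers(0, 2 ** 31 - 1))
    def test_linearity_in_the_error_history(self, c, seed):
        """Scaling the whole error history by c scales the PID trace by c."""
        g = PidGains()
        rng = np.random.default_rng(seed)
        errors = rng.normal(0, 5, 30)
        out1, out2 = [], []
        s1, s2 = correcting_state(), correcting_state()
        for e in errors:
            out1.append(pid_tick(-70.0 + e, s1, FLAT, g)[0])
            out2.append(pid_tick(-70.0 + c * e, s2, FLAT, g)[0])
        np.testing.assert_allclose(out2, np.array(out1) * c,
                                   rtol=1e-9, atol=1e-9)

    def test_integral_revert_is_exact(self):
        g = PidGains()
        st_ = correcting_state()
        pid_tick(-60.0, st_, FLAT, g)
        before = st_.e_sum
        pid_tick(-55.0, st_, FLAT, g)
        revert_integral(st_)
        assert st_.e_sum == pytest.approx(before)


class TestRouteOutput:
    def test_positive_pid_drives_red(self):
        light, sat = route_output(0.4, -60.0, -11.2, scale=1.0)
        assert (light.blue, light.red) == (0.0, pytest.approx(0.4))
        assert not sat

    def test_negative_pid_drives_blue_below_plateau(self):
        light, sat = route_output(-0.4, -60.0, -11.2, scale=1.0)
        assert (light.blue, light.red) == (pytest.approx(0.4), 0.0)
        assert not sat

    def test_blue_gated_off_above_plateau(self):
        light, sat = route_output(-0.4, -5.0, -11.2, scale=1.0)
        assert (light.blue, light.red) == (0.0, 0.0)
        assert sat   # demand unmet counts as saturation (integral freeze)

    def test_zero_pid_dark(self):
        light, sat = route_output(0.0, -60.0, -11.2)
        assert (light.blue, light.red) == (0.0, 0.0) and not sat

    def test_clipping_flags_saturation(self):
        light, sat = route_output(5000.0, -60.0, -11.2, scale=1.0)
        assert light.red == 1.0 and sat

    @settings(deadline=None, max_examples=200)
    @given(st.floats(-1e4, 1e4), st.floats(-95, 30))
    def test_channel_exclusivity(self, pid, vm):
        light, _ = route_output(pid, vm, -11.2, scale=1e-3)
        assert light.blue * light.red == 0.0


class TestClosedLoopLimit:
    def test_proportional_steady_state_error_matches_closed_form(self):
        """P-only control of a leaky-RC cell against a constant offset.

        Steady-state error must equal offset * g / (g + K) within 2%,
        K = K_P * scale being the proportional feedback strength.
        """
        g_leak, offset, K = 0.25, 8.0, 0.6
        gains = PidGains(K_P=1.0, K_I=0.0, K_D=0.0)
        sp = SetpointAP(values=np.full(10, -70.0 + offset), origin="generator")
        V, st_ = -70.0, correcting_state()
        for _ in range(3000):
            pid, st_ = pid_tick(V, st_, sp, gains)
            u = -K * pid                         # current-mode actuation
            V += 1.0 * (-g_leak * (V + 70.0) + u)
        expected = -offset * g_leak / (g_leak + K)  # V sits below the setpoint
        assert (V - (-70.0 + offset)) == pytest.approx(expected, rel=0.02)


class TestLe:
    def test_pacing_window_emits_pacing_pulse(self):
        model = named_triangular("t13")
        le = LEState()
        light, pid, sp, le = le_tick(0.0, -75.0, le, model, PidGains())
        assert light.blue == pytest.approx(0.5 / 1.5)
        assert light.red == 0.0

    def test_perfect_tracking_gives_zero_output_outside_pacing(self):
        model = named_triangular("t13")
        le = LEState()
        g = PidGains()
        for t in range(60):
            vm = model[min(t, len(model) - 1)] if t >= 10 else model.V_rest
            light, pid, sp, le = le_tick(float(t), vm, le, model, g)
        # V_m equals the enforced trajectory -> no corrective output
        assert light.blue == 0.0 and light.red == 0.0

    def test_model_must_cover_cycle(self):
        short = SetpointAP(values=np.full(400, -68.0), origin="generator")
        with pytest.raises(ValueError, match="shorter"):
            le_tick(0.0, -75.0, LEState(), short, PidGains())

    def test_logged_setpoint_rejected(self):
        logged = SetpointAP(values=np.full(1000, -68.0), origin="logged")
        with pytest.raises(ValueError):
            le_tick(0.0, -75.0, LEState(), logged, PidGains())
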