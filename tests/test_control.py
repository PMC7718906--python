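"""Proportional EMG-to-FES control chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fesemg as f
from fesemg.control import CalibrationError
from fesemg.signals import ParameterError


def _trace(x, fs=1000.0):
    return f.SignalTrace(np.asarray(x, float), fs)


def _profile(mvc=1.0, base=0.0, thr=0.1):
    return f.CalibrationProfile(mvc, base, thr)


class TestPowerEnvelope:
    def test_constant_input(self):
        env = f.power_envelope(_trace(np.full(1000, 3.0)), 200.0)
        np.testing.assert_allclose(env.samples, 9.0)

    def test_zeros(self):
        env = f.power_envelope(_trace(np.zeros(100)), 50.0)
        assert not env.samples.any()

    def test_sine_mean_square(self):
        t = np.arange(5000) / 1000.0
        x = 2.0 * np.sin(2 * np.pi * 50 * t)
        env = f.power_envelope(_trace(x), 500.0)
        assert env.samples[-1] == pytest.approx(2.0, rel=0.01)  # A^2/2


class TestCalibration:
    def test_zero_rest_gives_zero_baseline(self):
        mvc = f.generate_vemg(1.0, 1000.0, rms=1.0, seed=0)
        prof = f.calibrate(mvc, _trace(np.zeros(1000)))
        assert prof.baseline_power == 0.0

    def test_inseparable_traces_rejected(self):
        x = f.generate_vemg(1.0, 1000.0, seed=1)
        with pytest.raises(CalibrationError):
            f.calibrate(x, x)

    def test_power_scales_with_amplitude_squared(self):
        base = f.generate_vemg(2.0, 1000.0, rms=1.0, seed=2)
        mvc = base.with_samples(10.0 * base.samples)
        prof = f.calibrate(mvc, base)
        assert prof.mvc_power / np.max(f.power_envelope(base).samples) \
            == pytest.approx(100.0, rel=1e-6)


class TestReference:
    def test_boundaries_and_midpoint(self):
        prof = f.CalibrationProfile(mvc_power=10.0, baseline_power=2.0)
        assert f.to_reference(2.0, prof) == 0.0
        assert f.to_reference(10.0, prof) == 1.0
        assert f.to_reference(6.0, prof) == pytest.approx(0.5)

    def test_clamped_outside_range(self):
        prof = f.CalibrationProfile(mvc_power=10.0, baseline_power=2.0)
        assert f.to_reference(0.0, prof) == 0.0
        assert f.to_reference(100.0, prof) == 1.0


class TestDetectIntent:
    CFG = f.ControlConfig()
    PROFILES = {"edc": _profile(thr=0.2), "fds": _profile(thr=0.2)}

    def test_rest_when_both_below_threshold(self):
        intent, active = f.detect_intent(0.1, 0.15, self.CFG, self.PROFILES)
        assert intent == "rest" and not active

    def test_mutual_exclusion_keeps_larger_channel(self):
        intent, active = f.detect_intent(0.6, 0.4, self.CFG, self.PROFILES)
        assert intent == "extension" and active == {"edc"}

    def test_coactivation_allowed_when_exclusion_off(self):
        cfg = f.ControlConfig(mutual_exclusion=False)
        intent, active = f.detect_intent(0.6, 0.4, cfg, self.PROFILES)
        assert active == {"edc", "fds"} and intent == "extension"

    def test_hysteresis_holds_activation(self):
        cfg = f.ControlConfig(threshold_mode="double", off_threshold_factor=0.5)
        state = f.ControlState()
        state.edc.active = True
        # 0.15 is below the 0.2 on-threshold but above the 0.1 off-threshold
        intent, active = f.detect_intent(0.15, 0.0, cfg, self.PROFILES, state)
        assert "edc" in active
        state.edc.active = False
        _, active = f.detect_intent(0.15, 0.0, cfg, self.PROFILES, state)
        assert "edc" not in active


class TestPulsewidthMap:
    def test_below_threshold_zero(self):
        assert f.reference_to_pulsewidth(0.05, 0.1, 100, 300) == 0.0

    def test_full_reference_gives_max(self):
        assert f.reference_to_pulsewidth(1.0, 0.1, 100, 300) == 300.0

    def test_threshold_boundary_gives_min(self):
        assert f.reference_to_pulsewidth(0.1, 0.1, 100, 300) == pytest.approx(100.0)

    def test_monotone_in_reference(self):
        vals = [f.reference_to_pulsewidth(r, 0.1, 100, 300)
                for r in np.linspace(0, 1, 21)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSmoothPulsewidth:
    def test_holds_at_convergence(self):
        assert f.smooth_pulsewidth(55.0, 55.0, 0.1) == 55.0

    def test_ramp_rate_and_exact_arrival(self):
        pa = 0.0
        pa = f.smooth_pulsewidth(100.0, pa, 0.1)
        assert pa == pytest.approx(0.1)
        pa = 0.0
        for _ in range(1000):
            pa = f.smooth_pulsewidth(100.0, pa, 0.1)
        assert pa == pytest.approx(100.0)  # 1 s at Fs=1000 with eta=0.1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 300), min_size=1, max_size=200),
           st.floats(0.01, 5.0))
    def test_slew_bound_for_any_target_stream(self, targets, eta):
        pa = 0.0
        for pc in targets:
            nxt = f.smooth_pulsewidth(pc, pa, eta)
            assert abs(nxt - pa) <= eta + 1e-12
            pa = nxt


class TestController:
    def _controller(self, **cfg_kwargs):
        cfg = f.ControlConfig(**cfg_kwargs)
        profiles = {"edc": _profile(), "fds": _profile()}
        return f.Controller(cfg, profiles), cfg

    def test_zero_input_decays_and_stays_at_zero(self):
        ctl, _ = self._controller()
        ctl.state.edc.applied_pw = 5.0
        for _ in range(100):
            st, _, _ = ctl.step(0.0, 0.0)
        assert st.edc.applied_pw == 0.0 and st.fds.applied_pw == 0.0
        assert st.intent == "rest"

    def test_step_activation_ramps_at_eta_per_tick(self):
        ctl, cfg = self._controller()
        pa_prev = 0.0
        for _ in range(500):
            st, _, _ = ctl.step(1.0, 0.0)   # full-effort EDC
            delta = st.edc.applied_pw - pa_prev
            assert 0 <= delta <= cfg.eta + 1e-12
            pa_prev = st.edc.applied_pw
        assert pa_prev == pytest.approx(500 * cfg.eta, abs=cfg.eta)

    def test_steady_state_tracks_proportional_target(self):
        ctl, cfg = self._controller(eta=1.0)  # faster slew to reach steady state
        # constant extracted-EMG amplitude -> constant mid-level reference
        for _ in range(5000):
            st, _, _ = ctl.step(0.7, 0.0)
        ref = st.edc.reference
        target = f.reference_to_pulsewidth(ref, 0.1, cfg.pw_min, cfg.pw_max)
        assert abs(st.edc.applied_pw - target) <= cfg.eta

    def test_commands_respect_safety_limits(self):
        ctl, cfg = self._controller()
        for x in (0.0, 0.5, 5.0, 50.0):
            _, commands, _ = ctl.step(x, x / 2)
            for c in commands:
                assert 0 <= c.pulsewidth_us <= cfg.pw_max
                assert c.current_mA == cfg.current_mA
                assert c.frequency_hz == cfg.f_stim

    def test_missing_calibration_rejected(self):
        with pytest.raises(CalibrationError):
            f.Controller(f.ControlConfig(), {"edc": _profile()})


class TestFeedback:
    def test_equal_pulsewidths_zero(self):
        assert f.compute_feedback(120.0, 120.0, 300.0) == 0.0

    def test_extremes(self):
        assert f.compute_feedback(300.0, 0.0, 300.0) == 1.0
        assert f.compute_feedback(0.0, 150.0, 300.0) == -0.5


class TestTargetShape:
    def test_zero_flat_duration_triangular_with_empty_masks(self):
        shape = f.generate_target_shape(10.0, flat_duration_s=0.0, fs_display=100.0)
        assert not shape.extension_flat.any() and not shape.flexion_flat.any()

    def test_full_level_plateaus(self):
        shape = f.generate_target_shape(20.0, flat_level=1.0, flat_duration_s=4.0,
                                        fs_display=100.0)
        assert shape.value.max() == pytest.approx(1.0)
        assert shape.value.min() == pytest.approx(-1.0)
        np.testing.assert_allclose(shape.value[shape.extension_flat], 1.0)
        np.testing.assert_allclose(shape.value[shape.flexion_flat], -1.0)

    def test_mask_sizes_match_flat_duration(self):
        fs = 250.0
        shape = f.generate_target_shape(20.0, flat_duration_s=3.0, fs_display=fs)
        assert shape.extension_flat.sum() == pytest.approx(3.0 * fs, abs=2)
        assert shape.flexion_flat.sum() == pytest.approx(3.0 * fs, abs=2)

    def test_bounded(self):
        shape = f.generate_target_shape(15.0, flat_level=0.8, fs_display=100.0)
        assert np.all(np.abs(shape.value) <= 1.0)


class TestScoreTracing:
    def test_perfect_tracking(self):
        shape = f.generate_target_shape(10.0, fs_display=100.0)
        s = f.score_tracing(shape.value, shape)
        assert s["corr_feedback_target"] == pytest.approx(1.0)
        assert s["rmse_extension_flat"] == 0.0 and s["rmse_flexion_flat"] == 0.0

    def test_inverted_tracking(self):
        shape = f.generate_target_shape(10.0, fs_display=100.0)
        s = f.score_tracing(-shape.value, shape)
        assert s["corr_feedback_target"] == pytest.approx(-1.0)

    def test_constant_offset_rmse(self):
        shape = f.generate_target_shape(10.0, fs_display=100.0)
        s = f.score_tracing(shape.value + 0.07, shape)
        assert s["rmse_extension_flat"] == pytest.approx(0.07)
        assert s["rmse_flexion_flat"] == pytest.approx(0.07)

    def test_constant_feedback_flagged_degenerate(self):
        shape = f.generate_target_shape(10.0, fs_display=100.0)
        s = f.score_tracing(np.zeros_like(shape.value), shape)
        assert s["degenerate"]
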