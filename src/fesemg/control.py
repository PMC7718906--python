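"""Proportional EMG-driven FES control chain.

Two antagonist channels (wrist/finger extensor EDC and flexor FDS) are
processed tick-by-tick at the EMG rate (1 kHz):

1. smoothed power envelope of the filter-extracted EMG;
2. normalisation to a reference in [0, 1] against a maximum-voluntary-
   contraction (MVC) calibration;
3. movement-intent detection from the two references (single threshold by
   default, optional hysteresis and mutual exclusion of the channels);
4. linear mapping of the reference onto a computed pulsewidth ``p_c`` in
   [pw_min, pw_max] microseconds;
5. slew-rate-limited smoothing to the applied pulsewidth
   ``p_a[n] = p_a[n-1] + sign(p_c[n] - p_a[n-1]) * eta`` (``eta`` = 0.1 µs
   per 1 ms tick), which bounds pulsewidth changes for user comfort;
6. emission of stimulator commands and of the visual-feedback value
   ``(EDC_pw - FDS_pw) / pw_max``.

Tracing-task scoring (correlations and flat-region RMSE against a
trapezoidal target shape) is included for desk-scale evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signals import ParameterError, SignalTrace

__all__ = [
    "CalibrationProfile",
    "ControlConfig",
    "ChannelState",
    "ControlState",
    "StimCommand",
    "TargetShape",
    "CalibrationError",
    "power_envelope",
    "calibrate",
    "to_reference",
    "detect_intent",
    "reference_to_pulsewidth",
    "smooth_pulsewidth",
    "Controller",
    "compute_feedback",
    "generate_target_shape",
    "score_tracing",
    "run_tracing_session",
]

CHANNELS = ("edc", "fds")


class CalibrationError(ValueError):
    """MVC and rest recordings cannot be separated."""


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-channel MVC/rest power calibration."""

    mvc_power: float
    baseline_power: float
    activation_threshold: float = 0.1

    def __post_init__(self):
        if not self.mvc_power > self.baseline_power >= 0:
            raise CalibrationError("mvc_power must exceed baseline_power >= 0")
        if not 0 < self.activation_threshold < 1:
            raise ParameterError("activation_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ControlConfig:
    fs: float = 1000.0
    f_stim: float = 25.0
    eta: float = 0.1              # µs per tick
    pw_min: float = 100.0         # µs
    pw_max: float = 300.0         # µs
    current_mA: float = 20.0
    power_window_ms: float = 200.0
    threshold_mode: str = "single"   # or "double" (hysteresis)
    off_threshold_factor: float = 0.5  # off = factor * on threshold in double mode
    mutual_exclusion: bool = True
    dynamic_threshold: bool = False
    # per-intent threshold scaling used when dynamic_threshold is on:
    dynamic_threshold_table: dict = field(default_factory=lambda: {
        "rest": 1.0, "extension": 1.0, "flexion": 1.0})

    def __post_init__(self):
        if not self.eta > 0:
            raise ParameterError("eta must be positive")
        if not self.pw_max > self.pw_min >= 0:
            raise ParameterError("need pw_max > pw_min >= 0")
        if not 0 < self.current_mA <= 100:
            raise ParameterError("current outside the safety range")
        if self.threshold_mode not in ("single", "double"):
            raise ParameterError("threshold_mode must be 'single' or 'double'")


@dataclass
class ChannelState:
    applied_pw: float = 0.0
    computed_pw: float = 0.0
    reference: float = 0.0
    active: bool = False
    _env_acc: float = 0.0
    _env_buf: list = field(default_factory=list, repr=False)


@dataclass
class ControlState:
    edc: ChannelState = field(default_factory=ChannelState)
    fds: ChannelState = field(default_factory=ChannelState)
    intent: str = "rest"
    tick: int = 0


@dataclass(frozen=True)
class StimCommand:
    channel: str
    pulsewidth_us: float
    current_mA: float
    frequency_hz: float
    timestamp_s: float

    def __post_init__(self):
        if self.pulsewidth_us < 0:
            raise ParameterError("pulsewidth must be >= 0")


def power_envelope(trace: SignalTrace, window_ms: float = 200.0) -> SignalTrace:
    """Causal moving average of the squared samples (same length)."""
    win = max(1, int(round(window_ms * trace.fs / 1000.0)))
    sq = trace.samples ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    n = sq.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - win, 0)
    env = (csum[idx] - csum[lo]) / (idx - lo)
    return trace.with_samples(env, label=f"{trace.label}|power")


def calibrate(mvc_trace: SignalTrace, rest_trace: SignalTrace,
              window_ms: float = 200.0, threshold: float = 0.1) -> CalibrationProfile:
    """MVC power = max envelope during contraction; baseline = median at rest."""
    mvc_power = float(np.max(power_envelope(mvc_trace, window_ms).samples))
    rest_env = power_envelope(rest_trace, window_ms).samples
    baseline = float(np.median(rest_env))
    if mvc_power <= float(np.max(rest_env)):
        raise CalibrationError("MVC power indistinguishable from the resting recording")
    return CalibrationProfile(mvc_power=mvc_power, baseline_power=baseline,
                              activation_threshold=threshold)


def to_reference(power_value: float, profile: CalibrationProfile) -> float:
    """Baseline-subtracted, MVC-normalised power clamped to [0, 1]."""
    r = (power_value - profile.baseline_power) / (profile.mvc_power - profile.baseline_power)
    return float(np.clip(r, 0.0, 1.0))


def detect_intent(ref_edc: float, ref_fds: float, config: ControlConfig,
                  profiles: dict, state: ControlState | None = None) -> tuple[str, set]:
    """Movement-intent estimate from the two channel references.

    A channel is active when its reference exceeds its activation threshold
    (with hysteresis in double-threshold mode, using the previous activation
    held in ``state``); with mutual exclusion only the larger-reference
    channel stays active.  Returns (intent, active channel set) with intent
    one of ``extension`` (EDC), ``flexion`` (FDS) or ``rest``.
    """
    refs = {"edc": ref_edc, "fds": ref_fds}
    active = set()
    for ch in CHANNELS:
        thr = profiles[ch].activation_threshold
        if config.dynamic_threshold and state is not None:
            thr *= config.dynamic_threshold_table.get(state.intent, 1.0)
        if config.threshold_mode == "double" and state is not None:
            was = getattr(state, ch).active
            on_thr = thr
            off_thr = thr * config.off_threshold_factor
            is_on = refs[ch] >= (off_thr if was else on_thr)
        else:
            is_on = refs[ch] >= thr
        if is_on:
            active.add(ch)
    if config.mutual_exclusion and len(active) == 2:
        active = {"edc"} if refs["edc"] >= refs["fds"] else {"fds"}
    if active == {"edc"}:
        return "extension", active
    if active == {"fds"}:
        return "flexion", active
    if active:
        return "extension" if refs["edc"] >= refs["fds"] else "flexion", active
    return "rest", active


def reference_to_pulsewidth(reference: float, threshold: float,
                            pw_min: float, pw_max: float) -> float:
    """0 below threshold; linear map of [threshold, 1] onto [pw_min, pw_max] above."""
    if pw_max < pw_min:
        raise ParameterError("pw_max must be >= pw_min")
    if not 0 <= reference <= 1:
        raise ParameterError("reference must lie in [0, 1]")
    if reference < threshold:
        return 0.0
    if threshold >= 1.0:
        return pw_max
    frac = (reference - threshold) / (1.0 - threshold)
    return pw_min + frac * (pw_max - pw_min)


def smooth_pulsewidth(p_c: float, p_a_prev: float, eta: float) -> float:
    """Slew-limited update ``p_a = p_a_prev + sign(p_c - p_a_prev) * eta``.

    sign(0) is 0, so the applied pulsewidth holds once converged; when the
    target is within one step it snaps to the target rather than oscillating
    around it.
    """
    if not eta > 0:
        raise ParameterError("eta must be positive")
    delta = p_c - p_a_prev
    if abs(delta) <= eta:
        return p_c
    return p_a_prev + np.sign(delta) * eta


class Controller:
    """Two-channel proportional FES controller stepped at the EMG rate."""

    def __init__(self, config: ControlConfig, profiles: dict):
        for ch in CHANNELS:
            if ch not in profiles:
                raise CalibrationError(f"missing calibration for channel {ch!r}")
        self.config = config
        self.profiles = profiles
        self.state = ControlState()
        self._win = max(1, int(round(config.power_window_ms * config.fs / 1000.0)))

    def _envelope(self, ch_state: ChannelState, sample: float) -> float:
        buf = ch_state._env_buf
        buf.append(sample * sample)
        ch_state._env_acc += buf[-1]
        if len(buf) > self._win:
            ch_state._env_acc -= buf.pop(0)
        return ch_state._env_acc / len(buf)

    def step(self, edc_sample: float, fds_sample: float
             ) -> tuple[ControlState, list[StimCommand], float]:
        """Process one 1 ms tick of extracted EMG; returns (state, commands, feedback)."""
        cfg = self.config
        st = self.state
        refs = {}
        for ch, sample in zip(CHANNELS, (edc_sample, fds_sample)):
            chs = getattr(st, ch)
            power = self._envelope(chs, sample)
            chs.reference = to_reference(power, self.profiles[ch])
            refs[ch] = chs.reference
        intent, active = detect_intent(refs["edc"], refs["fds"], cfg,
                                       self.profiles, st)
        commands = []
        for ch in CHANNELS:
            chs = getattr(st, ch)
            if ch in active:
                chs.computed_pw = reference_to_pulsewidth(
                    chs.reference, self.profiles[ch].activation_threshold,
                    cfg.pw_min, cfg.pw_max)
            else:
                chs.computed_pw = 0.0
            chs.applied_pw = smooth_pulsewidth(chs.computed_pw, chs.applied_pw, cfg.eta)
            chs.active = ch in active
            commands.append(StimCommand(channel=ch, pulsewidth_us=chs.applied_pw,
                                        current_mA=cfg.current_mA,
                                        frequency_hz=cfg.f_stim,
                                        timestamp_s=st.tick / cfg.fs))
        st.intent = intent
        st.tick += 1
        feedback = compute_feedback(st.edc.applied_pw, st.fds.applied_pw, cfg.pw_max)
        return st, commands, feedback

    def run(self, edc: np.ndarray, fds: np.ndarray) -> dict:
        """Vector replay; returns per-tick logs."""
        edc = np.asarray(edc, float)
        fds = np.asarray(fds, float)
        if edc.size != fds.size:
            raise ParameterError("channel streams must have equal length")
        n = edc.size
        log = {k: np.empty(n) for k in
               ("ref_edc", "ref_fds", "pc_edc", "pc_fds", "pa_edc", "pa_fds", "feedback")}
        intents = []
        for i in range(n):
            st, _, fb = self.step(edc[i], fds[i])
            log["ref_edc"][i] = st.edc.reference
            log["ref_fds"][i] = st.fds.reference
            log["pc_edc"][i] = st.edc.computed_pw
            log["pc_fds"][i] = st.fds.computed_pw
            log["pa_edc"][i] = st.edc.applied_pw
            log["pa_fds"][i] = st.fds.applied_pw
            log["feedback"][i] = fb
            intents.append(st.intent)
        log["intent"] = np.array(intents)
        return log


def compute_feedback(pa_edc: float, pa_fds: float, pw_max: float) -> float:
    """Visual feedback ``(EDC_pw - FDS_pw) / pw_max`` in [-1, 1]."""
    if not pw_max > 0:
        raise ParameterError("pw_max must be positive")
    return (pa_edc - pa_fds) / pw_max


@dataclass(frozen=True)
class TargetShape:
    """Trapezoidal tracing target in [-1, 1] with flat-region masks."""

    time_s: np.ndarray
    value: np.ndarray
    extension_flat: np.ndarray   # boolean mask
    flexion_flat: np.ndarray


def generate_target_shape(duration_s: float, flat_level: float = 0.8,
                          flat_duration_s: float = 4.0, fs_display: float = 1000.0,
                          ramp_s: float | None = None) -> TargetShape:
    """Rest -> ramp up -> extension flat -> ramp down through rest -> flexion flat -> return.

    The profile is symmetric: the extension plateau sits at ``+flat_level``
    and the flexion plateau at ``-flat_level``; remaining time is split
    between the rest padding and linear ramps.
    """
    if duration_s <= 0 or flat_duration_s < 0 or not 0 <= flat_level <= 1:
        raise ParameterError("invalid target-shape parameters")
    n = int(round(duration_s * fs_display))
    t = np.arange(n) / fs_display
    if ramp_s is None:
        ramp_s = max((duration_s - 2 * flat_duration_s) / 6.0, 1e-9)
    # breakpoints: rest, up, ext flat, down, flex flat, return, rest
    pad = max((duration_s - 2 * flat_duration_s - 4 * ramp_s) / 2.0, 0.0)
    knots_t = np.cumsum([0.0, pad, ramp_s, flat_duration_s, 2 * ramp_s,
                         flat_duration_s, ramp_s, pad])
    knots_v = np.array([0.0, 0.0, flat_level, flat_level, -flat_level,
                        -flat_level, 0.0, 0.0])
    value = np.interp(t, knots_t, knots_v)
    ext = (t >= knots_t[2]) & (t < knots_t[3])
    flx = (t >= knots_t[4]) & (t < knots_t[5])
    return TargetShape(time_s=t, value=value, extension_flat=ext, flexion_flat=flx)


def score_tracing(feedback: np.ndarray, target: TargetShape,
                  emg_power_diff: np.ndarray | None = None) -> dict:
    """Tracing-task scores: Pearson correlations and flat-region RMSE.

    ``emg_power_diff`` is the signed difference of the two channels'
    extracted-EMG power envelopes (the "voluntary effort" trace).
    Correlations of constant sequences are returned as NaN and flagged.
    """
    fb = np.asarray(feedback, float)
    tv = target.value
    if fb.size != tv.size:
        raise ParameterError("feedback and target must have equal length")

    def _corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    out = {
        "corr_feedback_target": _corr(fb, tv),
        "rmse_extension_flat": float(np.sqrt(np.mean((fb - tv)[target.extension_flat] ** 2)))
        if target.extension_flat.any() else float("nan"),
        "rmse_flexion_flat": float(np.sqrt(np.mean((fb - tv)[target.flexion_flat] ** 2)))
        if target.flexion_flat.any() else float("nan"),
    }
    if emg_power_diff is not None:
        ed = np.asarray(emg_power_diff, float)
        if ed.size != fb.size:
            raise ParameterError("emg_power_diff must match feedback length")
        out["corr_feedback_emg"] = _corr(fb, ed)
    out["degenerate"] = bool(np.isnan(out["corr_feedback_target"]))
    return out


def run_tracing_session(edc: np.ndarray, fds: np.ndarray, target: TargetShape,
                        config: ControlConfig, profiles: dict) -> dict:
    """Replay a two-channel extracted-EMG stream against a tracing target."""
    ctl = Controller(config, profiles)
    log = ctl.run(edc, fds)
    power_diff = (power_envelope(SignalTrace(edc, config.fs), config.power_window_ms).samples
                  - power_envelope(SignalTrace(fds, config.fs), config.power_window_ms).samples)
    scores = score_tracing(log["feedback"], target, power_diff)
    return {"log": log, "scores": scores}
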