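"""Synthetic surface-EMG recordings contaminated by FES artifacts.

Voluntary EMG (vEMG) is modelled as band-limited Gaussian noise.  Each
stimulation pulse at ``f_stim`` contributes two artifacts to the recording:

* a 1-sample transient (direct pickup of the stimulus), whose sampled
  amplitude varies pulse-to-pulse because the stimulator and ADC clocks are
  not synchronised, and
* an m-wave — the stimulus-evoked compound muscle action potential — drawn
  from a two-parameter family ``alpha * exp(-t/tau) * w(t)`` where ``w`` is a
  fixed broadband multiphasic waveform, ``alpha`` scales the amplitude and
  ``tau`` (in samples) the decay.  ``alpha`` and ``tau`` are re-drawn
  uniformly for every pulse, making the artifact train non-stationary.

Optionally the first few samples after each pulse can be saturated to mimic
amplifier clipping.  The worst-case artifact magnitude is expressed through
``magnitude_ratio``: the peak absolute artifact amplitude divided by the
vEMG RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "SignalTrace",
    "ArtifactParams",
    "RecordingSim",
    "ParameterError",
    "ConfigurationError",
    "generate_vemg",
    "sample_mwave_params",
    "mwave_kernel",
    "generate_mwave_train",
    "add_stimulation_pulses",
    "apply_clipping",
    "contaminate",
    "make_recording",
]


class ParameterError(ValueError):
    """An operation received an argument outside its domain."""


class ConfigurationError(ValueError):
    """Inconsistent sampling/stimulation configuration (e.g. fs/f_stim not integer)."""


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (arbitrary units, µV-like).
    fs : float
        Sampling rate in Hz.
    label : str
        Free-text channel name.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ParameterError("trace must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("trace samples must be finite")
        if not self.fs > 0:
            raise ParameterError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SignalTrace":
        return SignalTrace(samples, self.fs, self.label if label is None else label)


# ---------------------------------------------------------------------------
# m-wave kernels
# ---------------------------------------------------------------------------

def _cmap_kernel(alpha: float, tau: float, length: int,
                 support: int = 32, chirp_tc: float = 10.0,
                 chirp_f0: float = 0.45) -> np.ndarray:
    """Broadband multiphasic m-wave: decaying envelope times a down-chirp.

    The instantaneous frequency starts at ``chirp_f0`` cycles/sample (the
    fast components directly following the stimulus) and relaxes with time
    constant ``chirp_tc`` into the slow main deflection.  ``alpha`` scales
    the amplitude and ``tau`` the exponential decay, so the family spanned
    by (alpha, tau) is low-dimensional: each m-wave is close to a linear
    combination of a few neighbouring ones, which is precisely what a
    frame-based least-squares predictor can exploit while a fixed comb
    filter cannot.
    """
    n = min(length, support)
    t = np.arange(n, dtype=float)
    phase = 2.0 * np.pi * chirp_f0 * chirp_tc * (1.0 - np.exp(-t / chirp_tc))
    wave = np.sin(phase)
    # cosine taper over the trailing quarter of the support
    q = max(1, support // 4)
    taper = np.ones(n)
    tail = t >= support - q
    taper[tail] = 0.5 * (1.0 + np.cos(np.pi * (t[tail] - (support - q)) / q))
    return alpha * np.exp(-t / tau) * wave * taper


def _gamma_kernel(alpha: float, tau: float, length: int,
                  support: int = 200) -> np.ndarray:
    """Single-lobe gamma-like m-wave ``alpha * t * exp(-t/tau)``.

    Peaks at ``t = tau`` with value ``alpha * tau / e``.
    """
    n = min(length, support)
    t = np.arange(n, dtype=float)
    return alpha * t * np.exp(-t / tau)


_KERNELS: dict[str, Callable[..., np.ndarray]] = {
    "cmap": _cmap_kernel,
    "gamma": _gamma_kernel,
}


def mwave_kernel(alpha: float, tau: float, length: int, kind: str = "cmap") -> np.ndarray:
    """Evaluate one m-wave kernel of at most ``length`` samples from pulse onset."""
    try:
        fn = _KERNELS[kind]
    except KeyError:
        raise ParameterError(f"unknown m-wave kernel {kind!r}; options: {sorted(_KERNELS)}")
    if length < 0:
        raise ParameterError("kernel length must be >= 0")
    return fn(alpha, tau, length)


@dataclass(frozen=True)
class ArtifactParams:
    """Stimulation-artifact model parameters.

    ``alpha`` and ``tau`` are drawn uniformly in mean ± halfrange per pulse
    (``tau`` in samples).  ``magnitude_ratio`` is the peak absolute artifact
    amplitude divided by the vEMG RMS; ``pulse_jitter`` is the uniform
    half-range (as a fraction of the nominal amplitude) of the sampled
    1-sample transient.  ``clip_window`` samples after each pulse may be
    saturated at ``clip_level`` when clipping is enabled.
    """

    f_stim: float = 25.0
    alpha_mean: float = 200.0
    alpha_halfrange: float = 20.0
    tau_mean: float = 20.0
    tau_halfrange: float = 5.0
    magnitude_ratio: float = 200.0
    pulse_jitter: float = 0.5
    clip_window: int = 0
    clip_level: float = 0.0
    kernel: str = "cmap"
    seed: int | None = None

    def __post_init__(self):
        if not self.f_stim > 0:
            raise ParameterError("f_stim must be positive")
        if self.alpha_halfrange < 0 or self.tau_halfrange < 0:
            raise ParameterError("halfranges must be non-negative")
        if not self.tau_mean - self.tau_halfrange > 0:
            raise ParameterError("tau_mean - tau_halfrange must stay positive")
        if not 0 <= self.clip_window <= 4:
            raise ParameterError("clip_window must be within 0..4 samples")
        if self.magnitude_ratio < 0:
            raise ParameterError("magnitude_ratio must be non-negative")
        if not 0 <= self.pulse_jitter <= 1:
            raise ParameterError("pulse_jitter must be within [0, 1]")

    def pulse_period(self, fs: float) -> int:
        """Samples between pulses; fs/f_stim must be an integer."""
        ratio = fs / self.f_stim
        period = round(ratio)
        if abs(ratio - period) > 1e-9 or period < 1:
            raise ConfigurationError(
                f"fs/f_stim = {ratio} is not an integer; comb/adaptive frames "
                "would misalign with the stimulation harmonics")
        return period


@dataclass(frozen=True)
class RecordingSim:
    """A paired clean/contaminated simulated recording."""

    clean: SignalTrace
    contaminated: SignalTrace
    pulse_indices: np.ndarray
    params: ArtifactParams

    def __post_init__(self):
        object.__setattr__(self, "pulse_indices",
                           np.asarray(self.pulse_indices, dtype=int))
        if len(self.clean) != len(self.contaminated) or self.clean.fs != self.contaminated.fs:
            raise ParameterError("clean and contaminated traces must match in length and fs")
        d = np.diff(self.pulse_indices)
        if d.size:
            period = d.min()
            if period < 1 or np.any(d % period):
                # gaps are allowed (stimulator switched off between bursts)
                # but pulses must stay on the periodic grid
                raise ParameterError("pulse_indices must lie on a periodic grid")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_vemg(duration_s: float, fs: float = 1000.0,
                  band: tuple[float, float] = (20.0, 450.0),
                  rms: float = 1.0, seed: int | None = None,
                  label: str = "vEMG") -> SignalTrace:
    """Band-limited Gaussian voluntary-EMG surrogate.

    White Gaussian noise is band-passed (4th-order Butterworth, applied
    forward-backward so the clean reference is not phase-shifted) and scaled
    to the requested RMS exactly.
    """
    if not duration_s > 0:
        raise ParameterError("duration_s must be positive")
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ParameterError(f"band {band} must satisfy 0 < low < high < fs/2")
    if rms < 0:
        raise ParameterError("rms must be non-negative")
    n = int(round(duration_s * fs))
    if rms == 0:
        return SignalTrace(np.zeros(n), fs, label)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = _sig.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, white)
    x *= rms / np.sqrt(np.mean(x ** 2))
    return SignalTrace(x, fs, label)


def sample_mwave_params(params: ArtifactParams, n_pulses: int,
                        seed: int | None = None) -> np.ndarray:
    """Draw per-pulse (alpha, tau) pairs, uniform in mean ± halfrange.

    Returns an ``(n_pulses, 2)`` array.
    """
    if n_pulses < 1:
        raise ParameterError("n_pulses must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    alphas = rng.uniform(params.alpha_mean - params.alpha_halfrange,
                         params.alpha_mean + params.alpha_halfrange, n_pulses)
    taus = rng.uniform(params.tau_mean - params.tau_halfrange,
                       params.tau_mean + params.tau_halfrange, n_pulses)
    return np.column_stack([alphas, taus])


def generate_mwave_train(fs: float, pulse_indices: Sequence[int],
                         param_pairs: np.ndarray, length: int,
                         kernel: str = "cmap") -> SignalTrace:
    """Superpose one m-wave kernel per pulse, each starting at its pulse index."""
    pulse_indices = np.asarray(pulse_indices, dtype=int)
    param_pairs = np.asarray(param_pairs, dtype=float)
    if pulse_indices.size and np.any(np.diff(pulse_indices) <= 0):
        raise ParameterError("pulse_indices must be strictly increasing")
    if param_pairs.shape != (pulse_indices.size, 2):
        raise ParameterError("need one (alpha, tau) pair per pulse")
    if pulse_indices.size and (pulse_indices[0] < 0 or pulse_indices[-1] >= length):
        raise ParameterError("pulse index outside the trace")
    out = np.zeros(length)
    for p, (a, t) in zip(pulse_indices, param_pairs):
        k = mwave_kernel(a, t, length - p, kind=kernel)
        out[p:p + k.size] += k
    return SignalTrace(out, fs, "m-wave train") if length else SignalTrace(out, fs)


def add_stimulation_pulses(trace: SignalTrace, pulse_indices: Sequence[int],
                           magnitude: float | np.ndarray) -> SignalTrace:
    """Add a 1-sample transient at each pulse index.

    ``magnitude`` may be a scalar (identical pulses) or one value per pulse.
    """
    pulse_indices = np.asarray(pulse_indices, dtype=int)
    if pulse_indices.size and (pulse_indices.min() < 0 or pulse_indices.max() >= len(trace)):
        raise ParameterError("pulse index outside the trace")
    magnitude = np.broadcast_to(np.asarray(magnitude, dtype=float), pulse_indices.shape)
    out = trace.samples.copy()
    out[pulse_indices] += magnitude
    return trace.with_samples(out)


def apply_clipping(trace: SignalTrace, pulse_indices: Sequence[int],
                   clip_window: int, clip_level: float) -> SignalTrace:
    """Saturate ``clip_window`` samples after each pulse at ±clip_level."""
    if not 0 <= clip_window <= 4:
        raise ParameterError("clip_window must be within 0..4 samples")
    if clip_level < 0:
        raise ParameterError("clip_level must be non-negative")
    if clip_window == 0:
        return trace
    pulse_indices = np.asarray(pulse_indices, dtype=int)
    out = trace.samples.copy()
    for p in pulse_indices:
        w = slice(p, min(p + clip_window, out.size))
        out[w] = np.clip(out[w], -clip_level, clip_level)
    return trace.with_samples(out)


def contaminate(clean: SignalTrace, params: ArtifactParams | None = None,
                seed: int | None = None,
                pulse_indices: Sequence[int] | None = None,
                reference_rms: float | None = None) -> RecordingSim:
    """Add the stimulation artifact train to an existing clean trace.

    One 1-sample transient (amplitude jittered pulse-to-pulse) plus one
    m-wave per pulse; the train is globally rescaled so its peak absolute
    amplitude equals ``magnitude_ratio * reference_rms`` exactly
    (``reference_rms`` defaults to the clean trace's RMS), then added.
    Clipping is applied afterwards when ``clip_window > 0``.

    ``pulse_indices`` defaults to the full periodic schedule starting at
    sample 0; an explicit subset (e.g. only the intervals during which the
    stimulator was actually active) may be given instead, but must keep a
    constant inter-pulse spacing equal to the stimulation period.
    """
    params = params or ArtifactParams()
    period = params.pulse_period(clean.fs)
    n = len(clean)
    if pulse_indices is None:
        pulses = np.arange(0, n, period)
    else:
        pulses = np.asarray(pulse_indices, dtype=int)
    if reference_rms is None:
        reference_rms = float(np.sqrt(np.mean(clean.samples ** 2)))

    rng = np.random.default_rng(None if seed is None else seed + 1)
    pairs = sample_mwave_params(params, max(pulses.size, 1), seed=int(rng.integers(2 ** 31)))
    if pulses.size:
        mwave = generate_mwave_train(clean.fs, pulses, pairs[:pulses.size], n,
                                     kernel=params.kernel)
        nominal_peak = np.max(np.abs(mwave_kernel(params.alpha_mean, params.tau_mean,
                                                  4 * period, kind=params.kernel)))
        amps = nominal_peak * rng.uniform(1.0 - params.pulse_jitter,
                                          1.0 + params.pulse_jitter, pulses.size)
        artifact = add_stimulation_pulses(mwave, pulses, amps).samples
    else:
        artifact = np.zeros(n)

    peak = np.max(np.abs(artifact))
    if peak > 0:
        artifact = artifact * (params.magnitude_ratio * reference_rms / peak)

    contaminated = clean.with_samples(clean.samples + artifact, label="contaminated")
    if params.clip_window > 0:
        contaminated = apply_clipping(contaminated, pulses,
                                      params.clip_window, params.clip_level)
    return RecordingSim(clean=clean, contaminated=contaminated,
                        pulse_indices=pulses,
                        params=replace(params, seed=seed))


def make_recording(duration_s: float = 35.0, fs: float = 1000.0,
                   params: ArtifactParams | None = None,
                   vemg_rms: float = 1.0, seed: int | None = None,
                   band: tuple[float, float] = (20.0, 450.0)) -> RecordingSim:
    """Simulate one contaminated recording.

    The clean trace is band-limited Gaussian vEMG at ``vemg_rms``; the
    artifact train is added by :func:`contaminate` with its peak scaled to
    ``magnitude_ratio * vemg_rms``.
    """
    params = params or ArtifactParams()
    clean = generate_vemg(duration_s, fs, band=band, rms=vemg_rms, seed=seed)
    return contaminate(clean, params, seed=seed, reference_rms=vemg_rms)
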