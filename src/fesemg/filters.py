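"""Causal artifact-removal filters for EMG recorded under FES.

Two stages, both streaming-capable:

* **Comb filter** ``x_c(n) = x(n) + b * x(n - L)`` with ``L = fs / f_stim``
  and ``b = -1``: its transfer-function zeros sit at the stimulation
  frequency and its harmonics, cancelling any component that repeats
  identically every ``L`` samples (the idealised transient artifact).

* **Frame-adaptive filter** ``y(n) = x_c(n) - sum_i b_i x_c(n - i L)``: the
  signal is buffered in non-overlapping frames of ``L`` samples aligned with
  the stimulation pulses; for every new frame, coefficients ``b_hat`` are
  re-estimated by least squares so that the combination of the previous
  ``M`` frames best predicts the current one, and the prediction — the
  stationary, stimulus-locked component, i.e. the artifact — is subtracted.
  The normal equations carry a small ridge term and are solved by LU
  factorisation.

Because the voluntary EMG is broadband and essentially independent between
frames, it survives the subtraction, while the m-wave train (a low-rank,
stimulus-locked family) is predicted and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.signal import lfilter

from .signals import ConfigurationError, ParameterError, SignalTrace

__all__ = [
    "CombFilterSpec",
    "AdaptiveFilterConfig",
    "FilterState",
    "DataError",
    "comb_delay",
    "comb_apply",
    "frame_signal",
    "solve_frame_coefficients",
    "FrameAdaptiveFilter",
    "adaptive_apply",
    "filter_chain",
]


class DataError(ValueError):
    """Input data unusable for the requested operation."""


def comb_delay(fs: float, f_stim: float) -> int:
    """Comb delay ``L = fs / f_stim`` in samples; must be an exact integer."""
    if fs <= 0 or f_stim <= 0:
        raise ParameterError("fs and f_stim must be positive")
    ratio = fs / f_stim
    L = round(ratio)
    if L < 1 or abs(ratio - L) > 1e-9:
        raise ConfigurationError(
            f"fs/f_stim = {ratio} is not an integer: the comb zeros would "
            "misalign with the stimulation harmonics")
    return L


@dataclass(frozen=True)
class CombFilterSpec:
    """Feed-forward comb ``x + b * x(n-L)``; ``b = -1`` notches f_stim and harmonics."""

    fs: float = 1000.0
    f_stim: float = 25.0
    b: float = -1.0

    @property
    def L(self) -> int:
        return comb_delay(self.fs, self.f_stim)


def comb_apply(trace: SignalTrace, spec: CombFilterSpec | None = None) -> SignalTrace:
    """Apply the comb causally with zero pre-history (real-time start)."""
    spec = spec or CombFilterSpec(fs=trace.fs)
    L = spec.L
    if L >= len(trace):
        raise ParameterError(f"trace length {len(trace)} must exceed comb delay {L}")
    taps = np.zeros(L + 1)
    taps[0] = 1.0
    taps[L] = spec.b
    y = lfilter(taps, [1.0], trace.samples)
    return trace.with_samples(y, label=f"{trace.label}|comb")


def frame_signal(trace: SignalTrace, L: int, offset: int = 0) -> np.ndarray:
    """Split into consecutive non-overlapping frames of ``L`` samples.

    Frames start at ``offset`` (``first pulse index mod L`` keeps them
    pulse-aligned); the trailing partial frame is discarded.  Returns an
    ``(n_frames, L)`` view-like array.
    """
    if L < 1:
        raise ParameterError("frame length must be >= 1")
    if L > len(trace):
        raise ParameterError("frame length exceeds trace length")
    if not 0 <= offset < L:
        raise ParameterError("offset must satisfy 0 <= offset < L")
    x = trace.samples[offset:]
    n_frames = x.size // L
    return x[: n_frames * L].reshape(n_frames, L)


def solve_frame_coefficients(current_frame: np.ndarray, prev_frames: np.ndarray,
                             regularization: float = 1e-8) -> np.ndarray:
    """Least-squares coefficients predicting the current frame from M previous ones.

    Minimises ``|| current - prev_frames.T @ b ||^2`` via the normal
    equations with a trace-scaled ridge term, solved by LU factorisation.
    ``prev_frames`` is ``(M, L)`` with row ``i-1`` holding the frame ``i``
    frames back.
    """
    current = np.asarray(current_frame, dtype=float)
    prev = np.asarray(prev_frames, dtype=float)
    if prev.ndim != 2 or current.ndim != 1 or prev.shape[1] != current.size:
        raise ParameterError("prev_frames must be (M, L) matching the current frame")
    if not (np.all(np.isfinite(current)) and np.all(np.isfinite(prev))):
        raise DataError("non-finite samples in frames")
    M = prev.shape[0]
    gram = prev @ prev.T
    lam = regularization * (np.trace(gram) / M if np.trace(gram) > 0 else 1.0)
    gram[np.diag_indices(M)] += lam
    rhs = prev @ current
    return lu_solve(lu_factor(gram), rhs)


@dataclass(frozen=True)
class AdaptiveFilterConfig:
    """Frame length ``L`` (40 short / 80 long), history depth ``M`` (default 6)."""

    L: int = 40
    M: int = 6
    warmup_policy: str = "pass-through"  # or "zero-output"
    solver_regularization: float = 1e-8
    store_coefficients: bool = True

    def __post_init__(self):
        if self.L < 1 or self.M < 1:
            raise ParameterError("L and M must be >= 1")
        if self.warmup_policy not in ("pass-through", "zero-output"):
            raise ParameterError("warmup_policy must be 'pass-through' or 'zero-output'")


@dataclass
class FilterState:
    """Streaming state: ring buffer of recent frames and coefficient history."""

    config: AdaptiveFilterConfig
    frames_processed: int = 0
    _ring: list = field(default_factory=list, repr=False)
    _residual: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    coefficient_history: list = field(default_factory=list, repr=False)

    @property
    def coefficients(self) -> np.ndarray:
        """Per-frame coefficient vectors, shape ``(n_filtered_frames, M)``."""
        if not self.coefficient_history:
            return np.empty((0, self.config.M))
        return np.vstack(self.coefficient_history)


class FrameAdaptiveFilter:
    """Streaming frame-based adaptive least-squares filter.

    Feed arbitrary chunks with :meth:`process`; output is emitted one whole
    frame at a time once ``M`` frames of history exist.  Identical total
    input produces bitwise-identical output regardless of chunking.
    """

    def __init__(self, config: AdaptiveFilterConfig | None = None):
        self.config = config or AdaptiveFilterConfig()
        self.state = FilterState(config=self.config)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        cfg = self.config
        st = self.state
        buf = np.concatenate([st._residual, np.asarray(chunk, dtype=float)])
        out: list[np.ndarray] = []
        L, M = cfg.L, cfg.M
        while buf.size >= L:
            frame, buf = buf[:L], buf[L:]
            if st.frames_processed < M:
                out.append(frame.copy() if cfg.warmup_policy == "pass-through"
                           else np.zeros(L))
            else:
                prev = np.array(st._ring[::-1])  # row 0 = most recent frame
                b = solve_frame_coefficients(frame, prev, cfg.solver_regularization)
                out.append(frame - prev.T @ b)
                if cfg.store_coefficients:
                    st.coefficient_history.append(b)
            st._ring.append(frame.copy())
            if len(st._ring) > M:
                st._ring.pop(0)
            st.frames_processed += 1
        st._residual = buf
        return np.concatenate(out) if out else np.empty(0)

    def flush(self) -> np.ndarray:
        """Emit the trailing partial frame unfiltered (pass-through) and reset it."""
        tail, self.state._residual = self.state._residual, np.empty(0)
        return tail


def adaptive_apply(trace: SignalTrace, config: AdaptiveFilterConfig | None = None,
                   offset: int = 0) -> tuple[SignalTrace, FilterState]:
    """One-shot adaptive filtering of a whole trace.

    Samples before ``offset`` and any trailing partial frame are passed
    through unchanged; warm-up frames follow ``config.warmup_policy``.
    """
    config = config or AdaptiveFilterConfig()
    if len(trace) < (config.M + 1) * config.L + offset:
        raise DataError(
            f"trace of {len(trace)} samples is shorter than the "
            f"(M+1)*L + offset = {(config.M + 1) * config.L + offset} needed")
    filt = FrameAdaptiveFilter(config)
    head = trace.samples[:offset]
    body = filt.process(trace.samples[offset:])
    tail = filt.flush()
    y = np.concatenate([head, body, tail])
    return trace.with_samples(y, label=f"{trace.label}|adaptive"), filt.state


def filter_chain(trace: SignalTrace, use_comb: bool = True,
                 config: AdaptiveFilterConfig | None = None,
                 spec: CombFilterSpec | None = None,
                 offset: int = 0) -> tuple[SignalTrace, FilterState]:
    """Comb (optional) followed by the adaptive filter, as run online."""
    config = config or AdaptiveFilterConfig()
    spec = spec or CombFilterSpec(fs=trace.fs)
    x = comb_apply(trace, spec) if use_comb else trace
    return adaptive_apply(x, config, offset=offset)
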