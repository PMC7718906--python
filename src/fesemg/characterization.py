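"""Average frequency-domain behaviour of the frame-adaptive filter.

The adaptive filter re-estimates its coefficients every frame; to
characterise it, the per-frame coefficient vectors stored during a run are
averaged and frozen into an equivalent sparse FIR

    h = [1, 0...0, -b1, 0...0, -b2, ..., -bM]        (M*L + 1 taps)

whose magnitude/phase response and group delay are then evaluated.  The
end-to-end ("effective") delay adds the one-frame buffering latency ``L``
on top of the group delay, because a frame can only be filtered once it has
been completely recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import freqz

from .filters import FilterState
from .signals import ParameterError

__all__ = [
    "FilterResponse",
    "StateError",
    "average_coefficients",
    "equivalent_fir",
    "frequency_response",
    "group_delay",
    "effective_delay_from_extrema",
    "characterize",
]

MAG_FLOOR_DB = -120.0


class StateError(RuntimeError):
    """Filter state does not contain what the operation needs."""


def average_coefficients(state: FilterState) -> np.ndarray:
    """Elementwise arithmetic mean of the stored per-frame coefficient vectors."""
    coeffs = state.coefficients
    if coeffs.shape[0] == 0:
        raise StateError("no coefficient history stored (run with store_coefficients)")
    return coeffs.mean(axis=0)


def equivalent_fir(avg_b: np.ndarray, L: int) -> np.ndarray:
    """Sparse FIR taps of the frozen-coefficient filter (M*L + 1 taps)."""
    avg_b = np.asarray(avg_b, dtype=float)
    if L < 1:
        raise ParameterError("L must be >= 1")
    M = avg_b.size
    taps = np.zeros(M * L + 1)
    taps[0] = 1.0
    for i, b in enumerate(avg_b, start=1):
        taps[i * L] = -b
    return taps


def frequency_response(fir: np.ndarray, fs: float,
                       n_points: int = 4096) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(freq_grid Hz, magnitude dB floored at -120, unwrapped phase rad)."""
    fir = np.asarray(fir, dtype=float)
    if n_points < fir.size:
        raise ParameterError("n_points must be >= number of taps")
    freq, h = freqz(fir, worN=n_points, fs=fs)
    mag_db = 20.0 * np.log10(np.maximum(np.abs(h), 10 ** (MAG_FLOOR_DB / 20)))
    phase = np.unwrap(np.angle(h))
    return freq, mag_db, phase


def group_delay(fir: np.ndarray, fs: float, n_points: int = 4096) -> np.ndarray:
    """Group delay -dphi/domega in samples, via the ratio-of-transforms identity.

    ``tau(w) = Re( DFT(n*h) / DFT(h) )``; bins where the response is
    numerically zero (inside a notch) are masked as NaN.
    """
    fir = np.asarray(fir, dtype=float)
    if n_points < fir.size:
        raise ParameterError("n_points must be >= number of taps")
    _, h = freqz(fir, worN=n_points, fs=fs)
    _, hr = freqz(np.arange(fir.size) * fir, worN=n_points, fs=fs)
    tau = np.full(n_points, np.nan)
    ok = np.abs(h) > 1e-9 * max(np.abs(h).max(), 1e-300)
    tau[ok] = np.real(hr[ok] / h[ok])
    return tau


def effective_delay_from_extrema(passband_max_delay: float, overall_max_delay: float,
                                 L: int, fs: float) -> tuple[float, float]:
    """(min_ms, max_ms): group-delay extrema plus the one-frame buffering delay L."""
    return (1000.0 * (passband_max_delay + L) / fs,
            1000.0 * (overall_max_delay + L) / fs)


@dataclass(frozen=True)
class FilterResponse:
    """Frozen average response of an adaptive filter run."""

    avg_coefficients: np.ndarray
    equivalent_fir: np.ndarray
    freq_grid: np.ndarray
    magnitude_db: np.ndarray
    phase_rad: np.ndarray
    group_delay_samples: np.ndarray
    passband_max_delay: float
    stopband_max_delay: float
    effective_delay_ms: tuple[float, float]
    L: int
    fs: float


def characterize(state: FilterState, fs: float, n_points: int = 4096,
                 passband_db: float = -3.0) -> FilterResponse:
    """Full characterisation from stored coefficients.

    The passband is taken as all frequencies with magnitude >= ``passband_db``
    (default -3 dB); the reported effective delay spans the passband maximum
    (minimum likely delay) to the overall maximum near the notches.
    """
    avg_b = average_coefficients(state)
    L = state.config.L
    fir = equivalent_fir(avg_b, L)
    freq, mag_db, phase = frequency_response(fir, fs, n_points)
    tau = group_delay(fir, fs, n_points)
    ok = np.isfinite(tau)
    passband = ok & (mag_db >= passband_db)
    pass_max = float(np.max(tau[passband])) if passband.any() else 0.0
    overall_max = float(np.max(tau[ok])) if ok.any() else 0.0
    eff = effective_delay_from_extrema(pass_max, overall_max, L, fs)
    return FilterResponse(avg_coefficients=avg_b, equivalent_fir=fir,
                          freq_grid=freq, magnitude_db=mag_db, phase_rad=phase,
                          group_delay_samples=tau,
                          passband_max_delay=pass_max,
                          stopband_max_delay=overall_max,
                          effective_delay_ms=eff, L=L, fs=fs)
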