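"""Filter-performance scoring: MRI, power reductions, average coherence.

Three instruments score an extracted signal against the clean reference:

* **MRI (muscle response index)**, in dB: ``10 log10( P_clean / (P_clean +
  P_residual) )`` with ``residual = test - clean``.  0 dB for perfect
  extraction, increasingly negative as residual artifact power grows.
* **Power reduction**, in dB: ``10 log10(P_num / P_den)`` — once against the
  clean reference (0 dB is perfect) and once against the artifact-laden
  input (strongly negative for effective filtering).
* **Average magnitude-squared coherence**: Welch estimate (Hann window,
  non-overlapping 1024-sample segments) averaged over the frequency grid
  excluding DC, reported together with the 95% confidence limit
  ``1 - 0.05**(1/(n_segments - 1))`` below which coherence is
  indistinguishable from that of independent signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import coherence as _welch_coherence

from .filters import (AdaptiveFilterConfig, CombFilterSpec, adaptive_apply,
                      comb_apply, filter_chain)
from .signals import ArtifactParams, ParameterError, RecordingSim, SignalTrace, make_recording

__all__ = [
    "FilterScores",
    "signal_power",
    "mri",
    "power_reduction",
    "coherence_spectrum",
    "coherence_confidence",
    "average_coherence",
    "score_filter_output",
    "run_simulation_study",
    "STUDY_VARIANTS",
]

DEFAULT_SEGMENT_LEN = 1024


def signal_power(trace: SignalTrace | np.ndarray) -> float:
    """Mean-square power."""
    x = trace.samples if isinstance(trace, SignalTrace) else np.asarray(trace, float)
    if x.size == 0:
        raise ParameterError("empty trace has no power")
    return float(np.mean(x ** 2))


def _paired(a, b):
    xa = a.samples if isinstance(a, SignalTrace) else np.asarray(a, float)
    xb = b.samples if isinstance(b, SignalTrace) else np.asarray(b, float)
    if xa.size != xb.size:
        raise ParameterError("traces must have equal length")
    return xa, xb


def mri(clean, test) -> float:
    """Muscle response index in dB; 0 iff the residual (test - clean) is zero."""
    c, t = _paired(clean, test)
    p_clean = float(np.mean(c ** 2))
    if p_clean == 0:
        raise ParameterError("MRI undefined for a zero-power clean reference")
    p_res = float(np.mean((t - c) ** 2))
    return 10.0 * np.log10(p_clean / (p_clean + p_res))


def power_reduction(numerator, denominator) -> float:
    """``10 log10(P_num / P_den)`` in dB."""
    n, d = _paired(numerator, denominator)
    p_den = float(np.mean(d ** 2))
    if p_den == 0:
        raise ParameterError("power reduction undefined for zero denominator power")
    p_num = float(np.mean(n ** 2))
    if p_num == 0:
        return -np.inf
    return 10.0 * np.log10(p_num / p_den)


def coherence_spectrum(a, b, segment_len: int = DEFAULT_SEGMENT_LEN,
                       fs: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Welch magnitude-squared coherence, Hann window, non-overlapping segments."""
    xa, xb = _paired(a, b)
    if xa.size < 2 * segment_len:
        raise ParameterError("need at least two full segments for coherence")
    if fs is None:
        fs = a.fs if isinstance(a, SignalTrace) else 1.0
    freq, coh = _welch_coherence(xa, xb, fs=fs, window="hann",
                                 nperseg=segment_len, noverlap=0, detrend=False)
    return freq, np.clip(coh, 0.0, 1.0)


def coherence_confidence(n_segments: int, level: float = 0.95) -> float:
    """95% (or ``level``) confidence limit for Welch coherence of independent signals.

    Closed form ``1 - (1 - level)**(1/(n_segments - 1))``.
    """
    if n_segments < 2:
        raise ParameterError("need at least 2 segments")
    if not 0 < level < 1:
        raise ParameterError("level must be in (0, 1)")
    return 1.0 - (1.0 - level) ** (1.0 / (n_segments - 1))


def average_coherence(a, b, segment_len: int = DEFAULT_SEGMENT_LEN,
                      fs: float | None = None,
                      level: float = 0.95) -> tuple[float, float]:
    """(mean coherence over the grid excluding DC, confidence limit)."""
    _, coh = coherence_spectrum(a, b, segment_len, fs)
    xa = a.samples if isinstance(a, SignalTrace) else np.asarray(a)
    n_segments = xa.size // segment_len
    return float(np.mean(coh[1:])), coherence_confidence(n_segments, level)


@dataclass(frozen=True)
class FilterScores:
    """One evaluation row: a filter variant scored against clean and input."""

    variant: str
    mri_x_db: float
    mri_y_db: float
    pr_clean_db: float
    pr_artifact_db: float
    avg_coherence: float
    coherence_conf95: float


def score_filter_output(variant: str, clean: SignalTrace, contaminated: SignalTrace,
                        extracted: SignalTrace,
                        segment_len: int = DEFAULT_SEGMENT_LEN) -> FilterScores:
    """Score one extraction against the clean reference and the raw input."""
    avg, conf = average_coherence(extracted, clean, segment_len)
    return FilterScores(
        variant=variant,
        mri_x_db=mri(clean, contaminated),
        mri_y_db=mri(clean, extracted),
        pr_clean_db=power_reduction(extracted, clean),
        pr_artifact_db=power_reduction(extracted, contaminated),
        avg_coherence=avg,
        coherence_conf95=conf,
    )


# variant name -> (use_comb, adaptive frame length or None for comb-only)
STUDY_VARIANTS: dict[str, tuple[bool, int | None]] = {
    "both-short": (True, 40),
    "adaptive-short": (False, 40),
    "both-long": (True, 80),
    "adaptive-long": (False, 80),
    "comb": (True, None),
}


def _extract(rec: RecordingSim, use_comb: bool, L: int | None,
             M: int = 6) -> SignalTrace:
    spec = CombFilterSpec(fs=rec.clean.fs, f_stim=rec.params.f_stim)
    if L is None:
        return comb_apply(rec.contaminated, spec)
    cfg = AdaptiveFilterConfig(L=L, M=M)
    offset = int(rec.pulse_indices[0]) % L if rec.pulse_indices.size else 0
    out, _ = filter_chain(rec.contaminated, use_comb=use_comb, config=cfg,
                          spec=spec, offset=offset)
    return out


def run_simulation_study(seed: int | None = None, duration_s: float = 35.0,
                         fs: float = 1000.0,
                         params: ArtifactParams | None = None,
                         vemg_rms: float = 1.0,
                         segment_len: int = DEFAULT_SEGMENT_LEN,
                         warmup_s: float = 1.0,
                         M: int = 6) -> pd.DataFrame:
    """Five-variant simulation study (the Table-1-style report).

    One contaminated recording is generated (with a ``warmup_s`` pre-roll so
    the adaptive filters are past their warm-up when scoring starts) and
    duplicated into every filter variant: comb+adaptive and adaptive-only at
    short (L=40) and long (L=80) frame lengths, plus the comb alone.  The
    scored window is the final ``duration_s`` seconds.
    """
    params = params or ArtifactParams()
    rec = make_recording(duration_s + warmup_s, fs, params, vemg_rms, seed)
    skip = int(round(warmup_s * fs))

    rows = []
    clean_w = rec.clean.with_samples(rec.clean.samples[skip:])
    cont_w = rec.contaminated.with_samples(rec.contaminated.samples[skip:])
    for variant, (use_comb, L) in STUDY_VARIANTS.items():
        out = _extract(rec, use_comb, L, M)
        out_w = out.with_samples(out.samples[skip:len(rec.clean)])
        rows.append(score_filter_output(variant, clean_w, cont_w, out_w, segment_len))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("variant")
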