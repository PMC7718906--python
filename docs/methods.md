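# Methods

## Problem and signal model

A muscle under FES produces a recording `x(n) = v(n) + a(n)` at
`Fs = 1000 Hz`, where `v` is the voluntary EMG and `a` the
stimulation-locked artifact train at `f_stim = 25 Hz` (one transient plus
one m-wave per pulse, repeating every `L = Fs/f_stim = 40` samples). The
vEMG is modelled as band-limited Gaussian noise; the artifact is two orders
of magnitude larger. The task is causal, online extraction of `v`.

## Filters

**Comb.** `x_c(n) = x(n) + b·x(n−L)` with `b = −1` and zero pre-history.
Any component that repeats identically every `L` samples is cancelled
exactly; broadband components pass (with power doubled for white inputs).
`Fs/f_stim` must be an exact integer, otherwise the notches miss the
artifact harmonics and the configuration is rejected.

**Frame-adaptive least squares.** The stream is cut into non-overlapping
pulse-aligned frames of `L` samples (`L = 40` short, `L = 80` long). For
each new frame `c` the previous `M = 6` frames `P` (M×L) give

    b̂ = argmin_b ||c − Pᵀb||²,

solved via the normal equations `(PPᵀ + λI) b̂ = Pc` by LU factorisation,
with a ridge term `λ = r·trace(PPᵀ)/M`, `r = 1e−8` by default. The ridge is
only there to keep degenerate systems (e.g. repeated or zero frames)
solvable; on generic data it perturbs the plain least-squares solution at
the 1e−8 relative level. The output frame is `c − Pᵀb̂`. The first `M`
frames have no history; they are passed through unchanged by default
(`warmup_policy="pass-through"`, flagged to callers by the frame counter) or
zeroed for control use. The filter is implemented as a streaming operator:
chunked and one-shot processing are bitwise identical.

Why this works: each m-wave is drawn from a low-dimensional family
(amplitude- and decay-modulated fixed waveform), so the current artifact lies
almost in the span of the six previous frames and is predicted and removed,
whatever its pulse-to-pulse variation; the vEMG is essentially independent
between frames and survives. The comb, by contrast, only removes the part
that is *identical* between consecutive periods, and fails exactly when the
artifact is non-stationary.

## Synthetic recordings

* **vEMG**: white Gaussian noise, 4th-order Butterworth band-pass 20–450 Hz
  (standard surface-EMG bandwidth below the 500 Hz Nyquist limit), applied
  forward-backward so the clean reference is zero-phase, then scaled to the
  requested RMS exactly.
* **m-wave kernel** (default `cmap`): `m(t) = α·e^{−t/τ}·sin(φ(t))` with
  instantaneous frequency chirping down from 0.45 cycles/sample with a
  15-sample time constant, 32-sample support, cosine-tapered tail. This is a
  fixed broadband multiphasic waveform whose amplitude (`α`, uniform
  200 ± 20) and decay (`τ`, uniform 20 ± 5 samples) are re-drawn per pulse:
  the early samples carry the fast components that directly follow the
  stimulus, giving way to the slow main deflection, as in recorded
  stimulus responses. The family is deliberately *low-rank but broadband*:
  pulse-to-pulse variation spreads over the whole EMG band (defeating the
  comb) while remaining predictable from a few recent frames (so the
  adaptive filter succeeds). A single-lobe gamma-like kernel
  `α·t·e^{−t/τ}` is available as `kernel="gamma"`; its spectrum is confined
  below ~30 Hz, which makes the comb look spuriously good (its residual
  vanishes over most of the band) — useful as a contrast case, not as the
  default.
* **Stimulus transient**: one sample per pulse, amplitude uniform within
  ±50% of the nominal kernel peak. The jitter models the unsynchronised
  stimulator and ADC clocks: each 1 ms sample catches a different phase of
  the µs-scale biphasic transient, so the recorded amplitude varies strongly
  pulse to pulse. (A perfectly repeating transient would be a degenerate
  special case that the comb alone removes exactly.)
* **Magnitude**: the artifact train is globally rescaled so its peak equals
  `magnitude_ratio × vEMG RMS`, default 200 — i.e. about 100× the visible
  (≈2·RMS) amplitude of a Gaussian EMG trace, representing the worst-case
  contamination regime; the resulting input MRI is ≈ −35 dB.
* **Clipping**: optionally the first ≤4 samples after each pulse (≤10% of
  the 40-sample interval) are saturated at a configurable level; off by
  default.
* The schedule starts at sample 0 and stays on the `L`-sample grid; gaps
  (stimulator off between bursts) are allowed for closed-loop use.

What the generator does **not** emulate: post-stimulus electrode-voltage
decay, physiological motor-unit structure, slow (fatigue-driven) m-wave
drift, amplifier noise, or movement artifacts. Passing tests therefore show
correctness of the algorithms and the expected behaviour under the stated
noise model, not performance on any particular patient recording.

## Evaluation

* **MRI** `= 10·log₁₀(P_clean/(P_clean + P_residual))`, residual = output −
  clean; 0 dB iff extraction is perfect. The formula is a reconstruction of
  the index's stated behaviour and is pluggable.
* **Power reductions**: output power vs clean (0 dB perfect) and vs the
  contaminated input (strongly negative for effective filtering). The two
  are linked by the identity `PR_clean − PR_artifact =
  10·log₁₀(P_input/P_clean)` for any output, which the tests verify.
* **Coherence**: Welch magnitude-squared coherence, Hann window,
  non-overlapping 1024-sample segments, averaged over the frequency grid
  excluding DC. With 35 s at 1 kHz this gives 34 segments and a 95%
  confidence limit `1 − 0.05^{1/33} = 0.086781`; averages above the limit
  are significant, independent signals fall below it.
* **Study protocol**: one recording is generated with a 1 s pre-roll and
  duplicated into five variants (comb+adaptive and adaptive-only at
  L = 40/80, comb-only); the pre-roll covers the adaptive warm-up, and the
  scored window is exactly the final 35 s, keeping 34 coherence segments.

## Characterisation and delay accounting

Per-frame coefficients stored over a run are averaged; the frozen filter is
the sparse FIR `[1, …, −b̄₁ at L, …, −b̄ᵢ at iL, …]` (M·L + 1 taps, M + 1
non-zero). Magnitude (floored at −120 dB), unwrapped phase and group delay
(ratio-of-transforms, singular notch bins masked) are evaluated on a
4096-point grid. The passband for delay reporting is everything above
−3 dB; "near the stopband" is everything else. The effective delay adds the
one-frame buffering latency: minimum = passband-maximum group delay + `L`,
maximum = overall maximum + `L`, in ms at `Fs`. With the group-delay extrema
9/73 samples (short) and 45/167 (long) this yields 49–113 ms and 125–247 ms.

## Control chain

1 ms tick per channel: causal 200 ms moving-average power envelope →
reference `(P − P_rest)/(P_MVC − P_rest)` clamped to [0, 1] (calibration:
MVC power = max envelope during maximal effort, baseline = median envelope
at rest, recorded with FES off) → activation when reference ≥ threshold
(default 0.1; optional hysteresis `double` mode and mutual exclusion of the
antagonist channels, both mirroring the configurable options of the
real-time system) → linear map of `[threshold, 1]` onto
`[pw_min, pw_max] = [100, 300] µs` → slew-limited smoothing with
`η = 0.1 µs`/tick, `sign(0) = 0` so the pulsewidth holds at convergence and
snaps to targets within one step (no limit-cycle chatter) → stimulator
command (25 Hz, configured current) and feedback `(EDC_pw − FDS_pw)/pw_max`.
The feedback is implemented as the normalised pulsewidth difference.
Commands never exceed `pw_max` or the configured current; the slew bound
`|p_a[n] − p_a[n−1]| ≤ η` holds for arbitrary inputs.

Tracing tasks use a trapezoidal target (rest → extension plateau → flexion
plateau → rest) and are scored by Pearson correlation of feedback against
target and against the extracted-EMG power difference, plus RMSE restricted
to the plateau masks; constant traces make the correlation undefined and
are flagged rather than scored.

## Numerical choices and edge cases

* Ridge default 1e−8 (trace-scaled); zero regularization reproduces plain
  least squares on well-conditioned frames.
* Comb pre-history is zero (causal start); the first `L` comb samples are
  therefore computed against silence.
* Frames are pulse-aligned via `offset = first pulse index mod L`;
  misaligned framing is permitted (the prediction only requires
  periodicity) but degrades artifact rejection.
* Determinism: every generator takes a seed; identical seeds give bitwise
  identical recordings, and the full pipeline is deterministic per seed.
* Scale: the default study (35 s, 875 frames, five variants) runs in ~1 s;
  the repeated-seed contrast checks use five seeds.

## Known limitations

* The adaptive filter's least-squares fit uses the vEMG-bearing frames as
  regressors, so a small fraction of voluntary power (of order M/L) is
  removed even without artifacts; MRI_y saturates near −1 dB rather than 0.
* The long filter (L = 80) spans two pulses per frame, doubling the
  artifact dimensionality seen by M = 6 regressors; it is consistently
  worse than the short filter here, matching its lower ranking in practice.
* Absolute study scores depend on the synthetic noise model; only the
  structure of the report, the confidence column, and the orderings
  (adaptive ≫ comb, short > long, adaptive above / comb below the 95%
  limit) are claimed as reproducible results.
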