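# fesemg

Extracting **voluntary EMG (vEMG)** from a muscle while it is being driven by
**functional electrical stimulation (FES)** is hard: every stimulation pulse
injects a sharp 1-sample transient and evokes an **m-wave** (the synchronised
compound muscle action potential), both orders of magnitude larger than the
voluntary signal. `fesemg` is a software-only, causal filtering and control
toolkit for this problem, aimed at neurorehabilitation-engineering research:

* a **comb filter** `x_c(n) = x(n) − x(n − L)`, `L = Fs/f_stim`, whose zeros
  sit on the stimulation frequency and its harmonics;
* a **frame-adaptive least-squares filter**
  `y(n) = x_c(n) − Σᵢ bᵢ x_c(n − iL)`, `i = 1…M`: the signal is buffered in
  pulse-aligned frames of `L` samples, and for every new frame the
  coefficients `b̂` are re-estimated (ridge-stabilised normal equations, LU
  solve) so that the `M` previous frames best predict the current one — the
  stimulus-locked artifact is predicted and subtracted, the broadband vEMG
  survives;
* a **synthetic-recording generator** (band-limited Gaussian vEMG, jittered
  stimulus transients, stochastic m-wave train with `α = 200 ± 20`,
  `τ = 20 ± 5`, worst-case ≈100× artifact magnitude) so everything is
  testable without recorded data;
* **evaluation instruments**: muscle response index (MRI, dB), power
  reductions, and Welch average magnitude-squared coherence with its 95%
  confidence limit `1 − 0.05^{1/(n_seg−1)}`;
* **filter characterisation**: averaged coefficients → equivalent sparse FIR
  → magnitude/phase response, group delay, and effective end-to-end delay
  (group delay + one-frame buffering);
* a **proportional FES control chain**: power envelope → MVC-normalised
  reference → intent detection over antagonist channels (EDC/FDS) →
  pulsewidth mapping → slew-limited smoothing
  `p_a[n] = p_a[n−1] + sign(p_c[n] − p_a[n−1])·η` (`η = 0.1` µs per 1 ms
  tick) → stimulator commands and visual feedback `(EDC_pw − FDS_pw)/pw_max`,
  plus tracing-task scoring.

## Worked example

Run the five-variant filter study on a worst-case synthetic recording
(35 s at 1 kHz, 25 Hz stimulation):

```python
import fesemg as f
df = f.run_simulation_study(seed=0, duration_s=35.0)
print(df.round(4))
```

```
                mri_x_db  mri_y_db  pr_clean_db  pr_artifact_db  avg_coherence  coherence_conf95
variant
both-short      -35.1733   -3.6101       2.9507        -32.2238         0.3564            0.0868
adaptive-short  -35.1733   -3.1998       2.4436        -32.7308         0.4011            0.0868
both-long       -35.1733  -10.1870      10.1156        -25.0588         0.1501            0.0868
adaptive-long   -35.1733   -8.4417       8.3399        -26.8346         0.1628            0.0868
comb            -35.1733  -21.0166      21.0236        -14.1508         0.0434            0.0868
```

Reading the row for the short adaptive filter used alone: the contaminated
input scores MRI_x = −35.2 dB (artifact power ≫ vEMG power); after filtering
the output MRI_y recovers to −3.2 dB, the extracted signal's power is within
2.4 dB of the clean reference, 32.7 dB below the contaminated input, and its
average coherence with the clean vEMG (0.40) is far above the 95%
significance limit (0.0868) — the extraction preserves the voluntary signal.
The comb filter alone leaves its output essentially incoherent with the
truth (0.043 < 0.0868): a fixed harmonic notch cannot track the
non-stationary m-wave train. The short (L = 40) filters outperform the long
(L = 80) ones.

The same operations are exposed on the command line
(`fesemg simulate | filter | characterize | evaluate | study | control`),
e.g. `fesemg study --seed 7 --out study.tsv`.

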