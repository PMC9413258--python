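# Methods notes

## Signal model and pipeline assumptions

All processing assumes a single trunk-mounted IMU sampled uniformly at
`fs` (default 100 Hz), with linear acceleration in m/s² on the vertical
(VT), mediolateral (ML) and anterior–posterior (AP) axes and angular
velocity in deg/s about the same axes (yaw, pitch, roll). Gravity is
assumed removed from the acceleration channels (the generator produces
zero-mean gait acceleration); all autocorrelation- and Fourier-based
features remove the sample mean explicitly, so a constant offset would not
change them.

## Low-pass filtering

Filter requirements are specified MATLAB-style as (passband edge in
π rad/sample, steepness, stopband attenuation). We map this to an IIR
design by placing the stopband edge at
`fpass + (1 − steepness)·(fnyq − fpass)` — i.e. the transition band is the
`(1 − steepness)` fraction of the passband-to-Nyquist span — choosing the
minimal Butterworth order that meets the attenuation there (0.1 dB passband
ripple budget), and applying it forward–backward (`sosfiltfilt`) for zero
phase. Zero phase matters: a causal filter would delay threshold crossings
and bias every segmentation boundary late.

At 100 Hz the two defaults come out as order-4 designs:

| use | passband | steepness | stopband | effective −3 dB |
|---|---|---|---|---|
| TUG channels | 0.01 π/sample (0.5 Hz) | 0.83 | 60 dB | ≈0.8 Hz |
| 6MWT acceleration | 0.02 π/sample (1.0 Hz) | 0.86 | 40 dB | ≈1.6 Hz |

Chair/turn pulses (sub-Hz content) pass essentially intact; gait
fundamentals near 1.5–2 Hz are attenuated but not removed by the 6MWT
filter, and since regularity and harmonic-ratio features are normalised
(autocorrelation by its zero lag, HR as a ratio of harmonic magnitudes)
they are insensitive to this scaling. An alternative reading of the
specification triple — stopband edge at `passband/steepness` — would
demand an order-≈40 filter with a ≈0.6 Hz stopband that annihilates the
entire gait band and with it every step-dependent feature; we use the
transition-width convention, which is the one the triple's (0.5, 1)
steepness range comes from. Both specs remain configurable.

## TUG segmentation

Pitch and yaw are rectified **then** filtered, then thresholded (25 deg/s
pitch for chair transfers, 32 deg/s yaw for turns); rectification first
makes detection independent of turn/rotation direction. Event boundaries
are the first/last samples of the above-threshold run — no peak centering.
Runs separated by <0.3 s are merged and runs shorter than 0.3 s dropped
(`merge_gap_s`, `min_event_s`): threshold crossing de-bounce that the
two-pulse contract needs on noisy trials; both configurable. A trial that
does not produce exactly two chair events bracketing exactly two turns is
rejected with the counts found, signalling an atypical trial rather than
guessing.

## TUG features

Statistics (RMS, min, max) are computed on the *filtered* signals
restricted to each sub-task interval; the resultant is taken of the
filtered components. Forward and backward gait are averaged *at the
feature level* (statistic per interval, then mean), and a subject's value
is the mean over their three trials — treating trials as repeated
measurements of one subject rather than independent samples, which also
prevents one subject straddling a train/test split.

## 6MWT features

* **Steps**: peaks of filtered VT acceleration above 25% of the signal's
  95th percentile, ≥0.3 s apart. The adaptive height makes detection
  amplitude-free; 0.3 s caps cadence at 200 steps/min.
* **Gait parameters**: stride length = `k_height × height` with
  `k_height = 0.83` (the usual ≈0.415·height per step), so distance
  = steps × stride/2 and speed = distance/duration. `k_height` is config.
* **SR/STR**: the autocorrelation is searched for its highest local maximum
  in a *step window* `step_time·[0.5, 1.5]` and a *stride window*
  `step_time·[1.5, 2.5]`, with `step_time` taken from the detected steps.
  Anchoring the windows on measured cadence (rather than fixed absolute
  windows) keeps the step peak and the stride peak from being confused when
  cadence varies across subjects; windows are explicit arguments of
  `regularity()`.
* **HR**: Fourier magnitudes at harmonics 1..20 of the stride frequency
  (10 even + 10 odd), computed over consecutive non-overlapping ten-stride
  windows and averaged. Which ten strides to use is otherwise arbitrary;
  averaging all full windows uses the whole walk. A vanishing denominator
  (pure even or pure odd signal) returns the sentinel `HR_CAP = 1e3`
  rather than infinity.
* **ApEn**: Pincus definition, embedding m=2, tolerance r=0.2·SD of the
  full series, Chebyshev distance, self-matches included. Computed on
  consecutive 30 s epochs and averaged: the pairwise count is quadratic in
  epoch length, and 30 s epochs bound it while leaving ≥50 strides per
  epoch. A constant series returns 0 by definition (all embedded vectors
  coincide). The kernel is numba-compiled when numba is importable, with a
  vectorised NumPy fallback.

## Synthetic cohort generator

Gait acceleration is a harmonic sum: a step-frequency fundamental, an
asymmetry term β at the stride frequency (which makes alternating steps
unequal, suppressing the step-lag autocorrelation peak and lowering SR
relative to STR), a roughness term γ at the third stride harmonic (odd,
hence lowering vertical/AP HR), and white noise. ML acceleration is
stride-frequency dominated, as in real trunk accelerometry. TUG trials are
two pitch half-sine pulses (1.5 s chair transfers) and two yaw half-sine
pulses (2.0 s turns) with gait acceleration between them; ground-truth
event intervals are the analytic spans where the noise-free pulse exceeds
the detection threshold, and chair-transfer vigour leaks into AP
acceleration (0.02 m/s² per deg/s) as trunk lean does in practice.

Cohort defaults mirror the target study design: 136 subjects, ages uniform
within decades at 36/64/36 counts, 33 M/103 F, three TUG trials and one
360 s walk each. The age coupling is linear with subject-level Gaussian
scatter: with age, gait slows (speed 1.25→0.80 m/s over ages 60→90, step
time 0.50→0.65 s), weakens (VT amplitude 1.55→1.10 m/s²), becomes less
symmetric and less smooth (β, γ 0.05→0.23), and turns and chair transfers
lose vigour (90→60 deg/s, 72→48 deg/s). No published amplitudes exist for
this protocol; these magnitudes are chosen to be physiologically plausible
for an elderly cohort and are plain configuration, not claims.

What the generator does **not** emulate: 30 m-course turnarounds inside
the 6MWT (the walk is treated as continuous gait, consistent with the
feature definitions), rest pauses, sensor drift or orientation error,
non-Gaussian artefacts, and aborted or multi-turn TUG trials. Passing
tests therefore demonstrate that the pipeline recovers known structure
from signals obeying its model — not performance on real recordings.

## Model

Subject-level 70/10/20 split by largest-remainder apportionment after a
seeded shuffle (136 → 95/14/27). Hyperparameters (learning rate
log-[0.01, 0.3], depth 2–8, 50–600 trees, subsample/colsample 0.5–1, L2
0–10) minimise validation MAE over 50 trials by default: the default
configuration is always trial 0 — so tuning can never be worse than the
default — followed by random exploration and Gaussian-process
expected-improvement proposals (Matérn-5/2 + white noise, 256-candidate
argmax). A pure random-search mode exists for speed. The final model is
refit on the training rows only; a content hash of the test rows is
verified unchanged between splitting and evaluation. FIS is XGBoost gain
importance normalised to sum to 1; features never split on (e.g.
zero-variance columns) score exactly 0.

## Problem sizes

The test suite runs scaled cohorts — 36 subjects with the same 1:2:1
decade structure, 60 s walks, 8 random search trials — for its multi-seed
model properties (10 seeds for the OT/OS/AG ordering, 5 for planted-signal
recovery), and the acceptance script runs the full 136-subject, 360 s
configuration once with 20 search trials. These sizes are the package's
own defaults for routine verification; all of them are parameters.

## Known limitations

* The harmonic-sum generator has a single global cadence per walk; real
  six-minute walks show cadence drift and fatigue effects, so ApEn values
  on synthetic data are lower than typical field values.
* HR windows assume the stride frequency estimated from mean step time is
  stationary over the walk.
* MAPE divides by true age, which is well-bounded here (≥60 y); the
  implementation refuses zero labels rather than returning infinities.
* The segmentation contract requires exactly two turns; pathological
  trials (aborted attempts, extra turns) are rejected, not repaired.
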