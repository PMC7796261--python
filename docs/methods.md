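# Methods

This note documents the models and numerical choices behind `ecgid`: what
each stage assumes, which parameters matter, what the synthetic cohort
generator does and does not emulate, and where the design was genuinely
open.

## Signal model and preprocessing

The package operates on single-lead (Lead-I) ECG sampled at ≥ 250 Hz
(default 500 Hz; 2 kHz is fully supported and used in the segmentation
arithmetic tests). All voltages are millivolts, indices 0-based, windows
half-open.

**Bandpass.** Zero-phase (forward–backward) Butterworth, default
0.5–40 Hz, order 4. The low cutoff removes baseline drift and the high
cutoff EMG/powerline components while leaving the QRS band (5–15 Hz
energy) untouched. Cutoffs and order are configurable; the forward–backward
pass doubles the effective order but preserves fiducial timing, which
matters because segmentation is anchored on the R peak.

**R detection.** A Pan–Tompkins detector: 5–15 Hz bandpass, five-point
derivative, squaring, 150 ms moving-window integration, then candidate
classification against running signal/noise levels with threshold
`noise + 0.25·(signal − noise)`, a 0.2 s refractory period, T-wave
rejection for candidates within 360 ms whose local slope is below half the
previous QRS slope, and a half-threshold search-back whenever the gap
exceeds 1.66× the running 8-beat RR average. Because the integration
window delays the energy peak relative to the R wave, accepted candidates
are re-anchored to the QRS-band maximum in a trailing 150 ms window and
finally snapped to the raw-signal maximum within ±25 ms. The detector is
purely deterministic. On clean synthetic records it is exact (sensitivity
and PPV 1.0 for 50–120 bpm); heavy artifact bursts can still hide beats,
which is precisely the situation the downstream threshold filter handles.

**QRS-sparing smoothing.** A centred moving average (default 25 ms)
applied everywhere except ±60 ms around each R peak, where samples are
kept bit-identical. The QRS complex carries most of the discriminative
morphology; smoothing it would blur exactly the information the
classifier needs, while the P/T regions tolerate (and benefit from)
averaging.

**Baseline removal.** One knot per RR interval, placed 66 % of the way
from one R peak to the next — inside the isoelectric TP segment, after the
T wave and before the next P wave — with level set to the median of ±25 ms
of samples. The piecewise-linear interpolation through the knots is
subtracted (held flat beyond the first/last knot). A first-order fit per
beat interval is deliberate: it tracks respiration-scale wander without
modelling (and thus without distorting) the in-beat morphology. The
operation is nearly idempotent; a second pass changes the signal by < 1 %
of the first pass's correction.

Stage order is frequency filter → R detection → QRS-sparing smoothing →
baseline removal; detection runs before smoothing so threshold adaptation
sees the unsmoothed QRS energy.

## Segmentation

Fixed fiducial windows: 0.3 s before to 0.4 s after each R peak
(`round(0.3·fs) + round(0.4·fs)` samples, R at `round(0.3·fs)`). Beats
whose window crosses a record edge are dropped and counted. At heart rates
above ~86 bpm neighbouring windows overlap; they are kept overlapping
rather than truncated, so every beat presents the same morphology to the
classifier. Length matching to a reference cycle uses linear resampling on
a uniform grid (endpoints preserved, R index rescaled) rather than
zero-padding, which would distort Euclidean distances between beats.

## Ideal cycle

`PeakStats` holds the per-wave mean voltage and mean sample location of
the five vertices over any annotated beat set (the built-in annotator
locates Q/S as extrema within ±60/70 ms of R, P and T in their
physiological windows). Vertices are bridged by

* order 1: `y(n) = y₁ + ω(n−x₁)`, `ω = (y₂−y₁)/(x₂−x₁)`, and
* order 2: `y(n) = y₁ + (y₂−y₁)·((n−x₁)/(x₂−x₁))²`,

both exact at the endpoints. The quadratic is normalized so that it
honours *both* endpoints — the naive `y₁ − ω(x₁−n)²` form does not reach
`y₂` at `x₂` and would break vertex exactness, which is the property the
whole construction exists for. Default order map: quadratic for
onset→P, P→Q, S→T and T→offset (rounded waves and shoulders), linear for
Q→R and R→S (straight QRS limbs); the onset/offset shoulders interpolate
from/to the 0 mV baseline, the natural level after baseline removal.
Vertex locations are rounded to the integer sample grid, making vertex
reproduction exact to machine precision, and the construction is linear in
the vertex voltages. Averaging across subjects is the default when
computing `PeakStats` from a mixed beat set; per-subject statistics are
obtained by simply passing a per-subject beat set.

## Adaptive threshold filter

Per subject: the static-state beat with the minimum Euclidean distance to
the ideal cycle (ties → lowest index) is the subject's *sample cycle*.
Each probe beat gets `S = ‖beat − sample‖₂`, and with `k = min S`,
`l = max S`, a beat passes iff `S < k + Th·step`. `S` is a distance —
smaller means more similar — so the filter keeps the *low*-S beats; the
admitted set always includes every beat tied at `S = k`, so classification
never receives an empty set even at `Th = 0`.

The threshold lives on an integer grid. When the spread `l − k` is at
least 1 (the typical case for mV-scale beats of ~350 samples), the grid
step is 1 raw distance unit and `Th ∈ {0, …, ⌈l−k⌉}`. When the spread is
sub-unit the integer grid between `k` and `l` would be empty, so the step
becomes one percent of the spread — the same rule on the
percentage-converted scale. `choose_threshold(min_pass)` returns the
smallest grid threshold whose pass rate reaches `min_pass` (default 0.7 in
the pipeline); it always terminates because one step past the grid maximum
admits every beat. Kept count is non-decreasing in `Th` by construction,
and the kept subset's mean distance never exceeds the full set's mean —
filtering can only concentrate the probe set around the subject's own
morphology.

## Classifiers

**LSTM.** Input beats are linearly down-sampled to `n_samples` (default
70, capped at 350) and grouped into frames of `frame_size` consecutive
samples (default 7), giving a 10-step recurrence — deep enough to traverse
P→QRS→T in order, shallow enough for stable full BPTT. Three stacked LSTM
layers of widths n, n/2, n/3 (n = hidden base, default the down-sampled
beat length), then two ReLU dense layers (default 400/200) with inverted
dropout 0.5, and a softmax output over enrolled subjects. Training is full
backpropagation through time with RMSprop (ρ = 0.9) at learning rate
0.001 for 10 epochs; the unstated batch size is set to 2, which on
enrollment-scale sets (tens of beats per subject) provides enough
parameter updates for convergence within those 10 epochs. The
implementation is pure numpy, gradient-checked against central finite
differences (relative error < 1e-5), and bit-deterministic under its seed
(weight init, shuffling and dropout all come from one Generator). Inputs
are scaled by the global training standard deviation. `LstmConfig.reduced()`
(hidden base 48, dense 64/32) is the configuration used by the desk-scale
experiments; 1- and 2-layer variants are selectable.

**Nearest template.** Stores each subject's mean enrolled beat and scores
a probe beat by softmax of negated Euclidean distances (temperature =
mean distance, so scores are scale-free). Fully deterministic; serves as
the fast default and as a cross-check on the LSTM.

Multi-beat probes average per-beat class scores and take the argmax (ties
→ lowest label). Scoring uses a one-vs-rest confusion tally — each 1:N
decision contributes one scored entry per enrolled class (correct: 1 TP +
N−1 TN; wrong: 1 FP, 1 FN, N−2 TN) — and accuracy
`(TP+TN)/(TP+FN+FP+TN)`. The tally convention is fixed and documented
here because several inequivalent conventions exist; its total always
equals decisions × classes.

## Synthetic cohort generator

Each subject template draws five peak voltages (P ∈ [0.08, 0.25], Q ∈
[−0.25, −0.05], R ∈ [0.8, 1.6], S ∈ [−0.40, −0.10], T ∈ [0.15, 0.45] mV)
and offsets (P ≈ −0.19 s, Q ≈ −0.04 s, S ≈ +0.04 s, T ≈ +0.28 s relative
to R), a heart rate in [55, 85] bpm and an RR jitter fraction in
[0.01, 0.04]. The single-beat waveform is built by the ideal-cycle
interpolation operator applied to the template's own vertices — the same
waveform model the normalization method assumes — and tiled at RR
intervals jittered by a truncated normal (±3 σ). Condition-dependent noise
is additive: sinusoidal baseline wander (0.04–0.16 mV, 0.25–0.4 Hz),
50/60 Hz hum (0.01–0.02 mV), white noise (0.01–0.03 mV), and
motion-artifact bursts of 0.3–1.0 s — Hann-windowed 1–10 Hz band-limited
noise — at 0 (sit), 2 (post-exercise), 4 (slide touch) and 8 (driving)
events/min with 0.3–0.8 mV amplitude. These scales are free parameters of
the emulator, chosen so that driving-grade records visibly corrupt a
minority of beats while sitting records stay clean; they are exposed via
`noise_profile_for(condition, **overrides)`.

The rhythm and the noise come from independent child streams of the seed,
so ground-truth R annotations are invariant to the noise profile — the
property that makes detector scoring against ground truth meaningful.

What the generator does **not** emulate: physiological dynamics (no
coupled-oscillator ECG model), heart-rate variability structure beyond
i.i.d. RR jitter, pathology, electrode-contact dropouts, or inter-session
morphology drift. Passing tests therefore demonstrate the pipeline's
correctness and the filter's selectivity under the stated noise model,
not clinical-grade performance on real ambulatory recordings.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen to keep
the statistics stable: detector scoring on 60 s records at four heart
rates; 10-subject cohorts with 30 s registration (sit) and 30 s
recognition (driving) records over 5 seeds for the identification
experiments, probes of 1–5 beats, both classifiers with the reduced LSTM
widths; 20 seeded 35-beat sets (30 clean + 5 corrupted at 10× noise) for
the artifact-rejection measurement; 50–200 random draws for the kernel,
vertex-exactness and monotonicity properties.

## Known limitations

* Real ECG normalization studies rest on multi-session acquisition;
  the generator's single-session model cannot expose enrollment drift.
* The Mahalanobis covariance is estimated from the enrollment beat stack
  with diagonal loading (1e-6 · trace/dim); with few beats it is heavily
  regularized and close to scaled-identity behaviour.
* The adaptive filter assumes the probe set contains at least a plurality
  of clean beats; if *every* probe beat is corrupted, the filter keeps the
  least-corrupted ones rather than rejecting the probe outright (open-set
  rejection is out of scope).
* WFDB-format I/O is not provided; records, peak sets, beat matrices and
  reports are exchanged as self-describing CSV/JSON.
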