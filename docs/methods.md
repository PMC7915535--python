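# Methods

`emid` decodes upper-limb movement intention from multichannel EEG in a
streaming setting: every 0.25 s it emits a probability distribution over
four articulation classes (elbow, wrist, hand, rest).  This note documents
the model, the processing pipeline, the synthetic study-protocol generator
the tests run against, and the numerical and design choices that were
genuinely open.

## Input representation

EEG channels are not an unordered list: neighbouring electrodes see
correlated potentials, and motor preparation has a lateralised, somatotopic
spatial structure.  Each time sample is therefore rearranged into a sparse
10 × 9 matrix whose cells mirror the cap geometry (most anterior row first,
left to right).  The packaged default grid places the 61 frontal / central /
parietal / temporal electrodes of a 10-10-style high-density motor cap
(`F3 … PPO2`); the 29 cells without an electrode are held at exactly 0.
Alternative caps can be supplied as a JSON mapping `{label: [row, col]}`.
Labels are matched case-insensitively after trimming, since EDF headers vary
in casing; recordings whose channel names cannot be mapped are rejected
rather than guessed at.

The classifier consumes the grid stream in non-overlapping **chunks** of 32
samples at 128 Hz (0.25 s, 32 × 10 × 9 = 2880 scalars), which sets the
decision period.

## Signal conditioning

The chain is deliberately minimal so that it can run sample-by-sample
online: a second-order IIR notch at 50 Hz (quality factor 30, configurable),
a 5th-order Butterworth bandpass 0.5–60 Hz (applied as second-order
sections), and decimation 512 → 128 Hz by keeping every 4th sample.  The
60 Hz band edge already band-limits the signal below the 64 Hz
post-decimation Nyquist, so no separate anti-aliasing stage is inserted.

Filtering defaults to causal (forward-only) application, matching the
online claim; `filter_mode: zero_phase` switches to forward–backward
filtering for offline analyses (results differ slightly between modes —
group delay versus symmetric smearing).  `StreamingPreprocessor` carries
the IIR state and the decimation phase across blocks, so blockwise and
whole-record causal processing agree to machine precision; this is tested.

## Movement onset detection and epoching

Training examples must contain *preparation* activity only.  Onset is read
from the synchronized kinematic trace (exoskeleton/glove), never from EEG,
and each training epoch is the one second of EEG ending immediately before
the detected onset — the half-open window `[onset − 128, onset)` at 128 Hz,
so the onset sample itself is always excluded.

The detector has two stages:

1. **Detection.**  The motion trace is low-pass filtered (causal
   Butterworth, 2 Hz) and the absolute first difference of the smoothed
   trace forms a speed envelope.  Smoothing *before* rectification matters:
   rectifying raw differences first leaves a noise-floor mean that swamps
   slow ramps.  Baseline mean and SD come from the second before the cue;
   the trial is accepted at the first post-cue run of at least
   `min_duration_s` (default 0.1 s) samples above `μ₀ + 5 σ₀`, back-tracked
   to the last sub-threshold sample.  The 0.1 s debounce is what makes the
   5 σ rule robust at 128 Hz, where a 25 ms run is only 3 samples.
2. **Localisation.**  The causal envelope is biased late by the filter's
   group delay (50–100 ms), which is material against a ±25 ms accuracy
   goal.  A changepoint model — flat baseline plus a cubic-smoothstep rise
   with unknown amplitude and rise time — is therefore least-squares fitted
   to the *raw* trace over a grid of candidate onsets (coarse-then-fine) and
   rise times (0.1–0.8 s); the best-fitting changepoint is the onset.  On a
   noise-free trace the stage-1 crossing is already exact (σ₀ = 0) and
   refinement is skipped.

Measured on synthetic kinematics (0.3 s smoothstep rise, 20 dB SNR,
512 Hz): ~97 % of detections within ±25 ms, bias ≈ −1 ms; inside the
full synthetic pipeline at 128 Hz, the maximum error observed is below
10 ms.  The detector is a documented stand-in validated only on synthetic
kinematics; its parameters are all exposed in `OnsetParams`.

Trials with no sustained crossing raise an error and are dropped — an
automated, reproducible replacement for manual trial review — and a QC
table flags onsets that precede the cue or fall beyond `cue + 4 s`.  "Rest"
trials have no kinematic event; their nominal onset is `cue + 1.5 s`
(configurable), placing the rest epoch inside the action period like the
movement classes.

The seven protocol classes merge onto four articulation targets
(flexion/extension → elbow, pronation/supination → wrist, open/close →
hand, rest → rest), giving 120/120/120/60 epochs from a balanced
10-run × 42-trial session.

## Model

**Encoder** (per chunk, 1 × 32 × 10 × 9 → ℝ^z):

| layer | default |
|---|---|
| Conv3d | 1 → 16 channels, kernel (5, 2, 2), stride 1, valid |
| ReLU + BatchNorm3d | eps 1e-5, momentum 0.1 |
| Conv3d | 16 → 32 channels, kernel (5, 1, 1), stride 1, valid |
| ReLU + BatchNorm3d | |
| MaxPool3d | kernel = stride = (3, 2, 2), floor sizes |
| Linear → ReLU → BatchNorm1d | flattened → z = 128 |

Convolution means cross-correlation (no kernel flip) without padding.  The
dense layer's input size is **derived from the actual post-pool shape at
construction** (4096 with the default kernels, 3072 with the (5, 2, 2)
second kernel, which is selectable via `EncoderConfig.conv2_kernel`) —
never hard-coded.  Batch norm over feature maps normalizes per channel
across the batch and all spatio-temporal positions; running estimates use
the unbiased variance (momentum 0.1) and drive eval mode.

**Classifier**: a single LSTM (z inputs, 64 hidden units; standard
input/forget/cell/output gating with σ/σ/tanh/σ) whose state persists
across chunks, then a 64 → 4 linear layer and softmax.  A fresh state is
all-zero; the reset policy is per-trial by default.

The layers are implemented directly in NumPy with explicit backward passes
(the architecture is small and fixed, and the whole forward stack is
validated against brute-force scalar-loop references in the tests; the full
network gradient was additionally checked against central finite
differences to ~5e-7 relative error during development).  Weights are
initialised uniform in ±1/√fan-in from a seeded generator, so every run is
reproducible.

## Training

Per-subject supervised training with Adam (β₁ = 0.9, β₂ = 0.999) and
label-smoothed categorical cross-entropy, default smoothing α = 0.2
(targets `(1−α)·onehot + α/4`; α = 0 recovers plain cross-entropy exactly).
Supervision is per chunk: all four decisions inside a 1 s epoch receive the
epoch's label, with the LSTM state reset at the epoch boundary.  This is
the natural reading of chunk-rate outputs trained on 1 s segments; an
epoch-end-only loss is the main alternative and would weight the sequence
tail more.

Model selection is a stratified 5-fold cross-validation repeated 3 times
with fresh initialisations (15 fits).  Stratification is by merged class —
it guarantees each fold keeps the 2:2:2:1 ratio and every class appears in
every fold; fold assignment is seed-reproducible and re-drawn per repeat.
Early stopping monitors the **validation loss** (the optimised quantity):
training stops after 10 consecutive non-improving epochs (max 100) and the
best-validation weights are restored.  The default batch size, 1024,
exceeds small synthetic datasets; the effective batch is
`min(batch_size, n_train)`.

`grid_search` exhaustively scores the searched axes — encoder output size
{512, 256, 128}, LSTM hidden {32, 64, 128}, learning rate {1e-3, 1e-4,
1e-5}, smoothing {0, 0.2, 0.4}; 81 combinations — by mean validation
accuracy over all (repeat, fold) entries.  Ties go to the configuration
with fewer parameters, then to grid order, making selection deterministic.
Batch size and convolutional channel counts are fixed-by-design knobs, not
grid axes.

## Evaluation

*Epoch-averaged accuracy* scores each of the four chunk decisions of a 1 s
epoch against the epoch label and averages over chunks and trials; chance
for four balanced classes is 25 %.

*Time-wise accuracy* synchronizes trials at the detected onset (t = 0) and
streams each trial's chunks through the model with the LSTM state carried
from the window start (default −3 s … +3 s).  Offsets label each chunk by
its end time, spaced 0.25 s.  The reset point is configurable: resetting at
−1 s makes the last four window decisions reproduce the epoch-averaged
protocol exactly (a tested invariant).  Starting the state at the window
start is the default because it matches the continuous online use case; the
reset policy used for any published curve should be stated alongside it.

A paired t-test helper (`paired_accuracy_test`, with a Shapiro–Wilk check
of the paired differences) is provided for per-subject accuracy
comparisons; no further inference machinery is in scope.

## One-vs-one panel aggregation

To compare a direct 4-class decoder against pairwise-classifier baselines,
a 21-pair one-vs-one panel over the 7 protocol classes is collapsed onto
the 4 articulation classes — each merged pair inheriting the **maximum**
accuracy among the original pairs it absorbs — and the multiclass accuracy
of the 6-classifier panel is estimated by Monte-Carlo majority vote
(default 10 000 simulations, seeded): a relevant classifier votes for the
true class with probability equal to its accuracy; vote-count ties are
broken uniformly.

A pairwise accuracy says nothing about a classifier's behaviour on samples
from neither of its classes, so **irrelevant classifiers vote uniformly
between their two classes** — the minimal-assumption choice, flagged here
because other conventions (e.g. always-wrong or class-prior-weighted
votes) change the aggregate.  The class prior of the simulated samples is
uniform over the merged classes by default; a 2:2:2:1 prior matching the
balanced 7-class design is available via `class_prior`.  `exact_aggregate`
enumerates all 2^6 joint vote outcomes (practical up to 5 classes, ties
split in expectation) and serves as the exact oracle for the Monte-Carlo
path; the estimate converges to it at the binomial rate.

## Synthetic study protocol

The generator emulates the structure of a cued motor-execution session so
every downstream stage is testable without external data: 10 runs × 42
trials balanced over 7 classes; per trial a beep at 0 s, cue at 2 s, a
uniform 0.5–1.5 s waiting time, 3 s of movement, and 2–3 s inter-trial
rest; 61 grid channels plus one kinematic trace at 512 Hz.

Signal content per channel: unit-normalised 1/f ("pink") noise, a
spatially shared slow drift (same 1/f character, amplitude `drift_rel`
times the noise SD), 50 Hz line interference with per-channel phase, and a
class-dependent pre-movement signature — a linear negative ramp reaching
`template_amp` (8 µV) at movement start on a small left-central electrode
group, held through the movement and released afterwards, emulating the
readiness-potential build-up that precedes voluntary movement.  The three
articulations load disjoint groups (elbow on the *1-column around C1, wrist
on the *3 column around C3, hand on the *5 column around C5); the two
classes of one articulation share their core electrode but emphasise
anterior versus posterior neighbours; rest has no signature.

`snr_db` is defined on **decoder-visible** quantities: the peak amplitude
the signature retains after the notch + bandpass chain (the 0.5 Hz
high-pass reduces the 8 µV ramp to a ~0.55 µV biphasic wave; computed by
passing the template through the chain at configuration time) over the
in-band noise SD.  An SNR defined on raw amplitudes would be dominated by
out-of-band power that the decoder never sees.  The default, 10 dB, makes
the four merged classes separable by a nearest-class-centroid probe with
accuracy ≳ 0.95 — a deliberately easy regime that verifies the learning
machinery end-to-end.

The kinematic trace is Gaussian sensor noise (SD 0.02, movement plateau
1.0) plus a 0.3 s smoothstep rise at onset, giving a sharp, known ground
truth for detector scoring.

**What passing tests do and do not show.**  The generator reproduces the
protocol's bookkeeping, spectra coarse enough to exercise the filters, and
a learnable spatial signature.  It does not model volume conduction, real
MRCP morphology or inter-subject variability, artifacts (EMG, EOG, motion),
or non-stationarity.  A model that reaches high accuracy here has a correct
pipeline and optimisation loop; nothing follows about its accuracy on real
EEG, where published per-subject accuracies for this task sit near 40–80 %
against a 25 % chance level.

## Problem sizes used by the test suite

The shipped tests run the full protocol-scale pipeline (one 10-run subject,
420 epochs) and train a reduced decoder (4/8 conv channels, z = 32, 16
hidden units, batch 64) with single-repeat 5-fold CV capped at 12 training
epochs — sizes chosen so the whole suite runs on one CPU in minutes while
still exercising every code path at protocol scale.  The full-size model
(16/32 channels, z = 128, 64 hidden, 3 × 5-fold CV, 100-epoch budget) is
the library default and runs the same code.

## Known limitations

- EDF is read (via `mne`) but not written; continuous outputs are
  delimited-text matrices.
- Causal versus zero-phase filtering changes epochs slightly; the package
  defaults to causal and records the mode in every run manifest.
- The onset detector's changepoint model assumes a smooth monotone rise;
  kinematics with slow drifts before movement or multi-phasic starts would
  need different `OnsetParams` (or `refine=False` plus manual review).
- `exact_aggregate` is exponential in the number of pairs and is capped at
  5 classes by default.
- Training is plain (no dropout, no weight decay by default, single LSTM
  layer), matching the deployed configuration; `l2_penalty` is honoured
  (Adam weight decay), while a nonzero `lstm_dropout` is rejected at
  configuration time rather than silently ignored.
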