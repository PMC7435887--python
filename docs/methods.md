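# Methods

## Problem setting

Enrolment registers a set of subjects from single-channel ECG; at test time
the system must identify which enrolled subject produced a probe signal, or
verify a claimed identity. Both decisions are built from a window-level
similarity score `S(p, i, w) ∈ [0, 1]` — predictor `p`, true subject `i`,
window `w` — where 0 marks the most probable identity. Two score generators
and one classifier are implemented.

## Preprocessing

Records pass through: centered moving-average removal (default 1 s; baseline
wander), convolution with a unit-sum Hanning kernel (default 25 ms;
high-frequency noise), and division by a centered moving absolute maximum
(default 3 s; local gain control, output in [−1, 1]). The recurrent path
additionally winsorizes amplitudes at the symmetric 0.5% histogram quantiles
(isolated artifacts would otherwise consume quantization range) and
quantizes by min–max scaling onto `{0 … SD−1}` with `SD = 512` levels,
rounding half away from zero so results do not depend on the platform's
banker's rounding. The convolutional path keeps the real-valued signal; its
chain stops after the absolute-maximum normalization.

Signals are then segmented into windows of `W` samples with fractional
overlap (step `max(1, round(W·(1−overlap)))`). Defaults follow the
benchmark regimes: `W = 512`, overlap 0.67 for the recurrent path and
`W = 256`, overlap 0.67 for the convolutional path, at 250 Hz. Heavily
corrupted windows are removed per subject by a robust z-score
(median/MAD, threshold 3) on the window standard deviation — corrupted
windows reveal themselves through anomalous amplitude spread; the rejection
threshold is configurable because the appropriate aggressiveness depends on
acquisition quality.

The moving-window lengths are conventional ECG choices; they are exposed in
`PreprocessConfig` and converted from seconds by `PreprocessConfig.for_fs`.
Winsorization (rather than sample deletion) was chosen for clipping because
it preserves window alignment.

R peaks for the fiducial stream are found by a derivative–square–integrate
detector (5–20 Hz band-pass, 150 ms integration, 0.3 s minimum spacing,
refinement to the band-passed maximum). Detection runs on each whole record
— full context makes it far more reliable than per-window runs — and peaks
are then mapped into window coordinates; each window's first peak anchors a
0.7 s cycle crop, zero-padded at window edges. Windows containing no peak
are excluded from the fiducial stream and scored by the non-fiducial stream
alone.

## Train/test protocol

Fraction mode enrols on the first 33% of each record (boundary at
`floor(0.33·n)` samples) and probes on the rest; any window straddling the
boundary is dropped so the sets share no sample. Cross-session mode enrols
on one whole session and probes on the whole other session, mirroring
two-visit acquisition campaigns. The 33% is interpreted as a fraction of
samples (not of windows).

## Recurrent score generator

Per subject: embedding (`SD × 32` default) → three stacked GRUs (64 hidden
units default) → dense layer to `SD` logits. The architecture couples a
softmax output with a mean-squared next-sample loss; these are connected
through the softmax expectation `ŷ_n = Σ_k k·P(k)`, which makes the loss
differentiable and lets the identical quantity serve as the test-time
prediction error `e = (1/W) Σ (ŷ_n − y_n)²` (targets are the input shifted
by one sample, on the quantized amplitude scale). Alternative readings
(one-hot MSE) were considered and rejected because they decouple training
from the scoring statistic. Training uses RMSProp (lr 1e-3), mini-batches of
32 windows, and early stopping on a 10% held-out slice with the
best-validation parameters restored. Scores are errors normalized by the
worst predictor per window, `S = e / max_p e`, so each column's maximum is
exactly 1. Predictors are independent per subject: enrolling a new subject
never retrains the others.

## Convolutional score generator

Two streams: non-fiducial (whole window) and fiducial (R-centered cycle,
two fewer blocks). Blocks are causal dilated 1-D convolutions with 24
kernels of size 4, batch normalization, and ReLU; dilation schedules default
to powers of two descending to 1, giving a stack receptive field
`1 + 3·Σdilations` which is validated against the input length at build
time. Each stream ends in a 256-unit dense layer and a per-subject logit
layer, trained independently with Adam (lr 1e-3) on categorical
cross-entropy against one-hot subject targets, batches of 64, early-stopped
like the recurrent path. After training, batch-norm statistics are
recalibrated in one pass over the training data with the final weights:
running averages otherwise lag the weights they normalize for, and the
mismatch compounds through the stack at inference. Stream logits are fused
by elementwise sum; the fused vector is softmaxed (guaranteeing the
non-negativity the score map needs) and mapped to
`S = 1 − o/max(o)`, so the top class scores exactly 0.

## Relative Score Threshold Classifier

Aggregation takes consecutive, non-overlapping blocks of `B` windows in
window order and keeps the per-predictor minimum; a trailing remainder
shorter than `B` is dropped. Columns are then min–max normalized over
predictors; all-equal columns map to all zeros (logged) and fall to the tie
rule. Identification is `argmin_p` with ties broken deterministically toward
the lowest predictor index; authentication accepts a claimed identity when
its normalized score is ≤ δ (acceptance at equality).

## Evaluation

Identification: confusion matrix, accuracy, macro-averaged per-class
sensitivity and specificity. Authentication: per enrolled individual,
genuine scores are the subject's own normalized batch scores and impostor
scores everyone else's against that predictor; sweeping δ over all midpoints
of consecutive distinct observed scores plus {0, 1} realizes the exact
step-function ROC with FNR non-increasing and FPR non-decreasing. The EER is
read at the FNR = FPR crossing, linearly interpolated in δ between sweep
points (an interpolation-free mode returns `(FNR+FPR)/2` at the sweep point
minimizing their gap, which the tests compare against a brute-force scan).
Cohort EER is summarized as mean ± population standard deviation across
individuals. Batch sweeps convert `B` to seconds of signal per decision via
the overlap-corrected `B·W·(1−overlap)/fs + W·overlap/fs`.

## Synthetic cohorts

Each subject is five Gaussian bumps (P, Q, R, S, T) with per-subject
amplitudes, offsets relative to R, and widths drawn from physiologically
plausible uniform ranges; beats advance by a per-subject mean RR (stratified
across the cohort over 0.7–1.1 s, so any two subjects are guaranteed to
differ) plus Gaussian jitter (30 ms). Sinusoidal baseline wander (0.1 a.u.,
0.25 Hz) and white noise (0.03 a.u.) are superimposed. `separation` scales
all inter-subject dispersion around the range midpoints (0 collapses the
cohort); `session_drift` perturbs every wave parameter multiplicatively by
up to ±drift between sessions, emulating electrode-placement and
physiological change between visits months apart. All randomness flows from
one cohort seed through per-(subject, session, purpose) spawn keys, so any
record is reproducible in isolation. True beat times are emitted as ground
truth for the R-peak detector tests.

What the generator does **not** emulate: arrhythmic events, non-stationary
noise (motion artifacts, electrode pops), pathological morphologies, and
realistic long-term drift. Passing tests therefore demonstrate that the
pipeline's machinery behaves as specified and that its qualitative behaviors
(batch aggregation helps; session drift hurts) emerge, not that the
headline accuracies would transfer to clinical or off-person recordings.

## Experiment sizes and defaults

The bundled experiments use cohorts sized to make every behavior measurable
on a single CPU in minutes: 5 subjects × 240 s at 250 Hz for the
convolutional path (about 230 training and 470 probe windows per subject)
with a 5-block non-fiducial stream, and 3 subjects × 240 s for the
recurrent path with a reduced predictor (embedding 16, 32 hidden units,
RMSProp at 3e-3, 30 epochs). These are deliberately small versions of the reference
architecture (which uses 6 blocks and wider recurrent layers on
multi-subject public databases); the full-size settings remain available
through configuration.

## Numerical and degenerate-input choices

* Quantization of a constant signal is rejected (the min–max map is
  undefined); all-zero absolute-max windows normalize to 0.
* Score columns where every predictor ties (all-zero errors, all-equal
  outputs) map to all zeros and are logged, never raised.
* Gradients of every layer are hand-derived; the test suite verifies each
  against central finite differences at tolerance 1e-5.
* The convolutional score map gives the per-window winner a score of exactly
  0, so batch minima can tie at 0 across predictors; with the deterministic
  lowest-index tie rule, batch aggregation only strictly improves accuracy
  once window-level errors are rare — visible in the batch sweeps.

## Known limitations

* Single channel only; no streaming acquisition.
* The noisy-window rejection is a robust z-score on window standard
  deviation, a deliberately simple stand-in for clustering-based artifact
  detectors; it targets gross amplitude artifacts only.
* Training is CPU-bound numpy; the defaults are sized for cohorts of a few
  subjects, not for databases of dozens.
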