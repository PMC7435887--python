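# ecgid — ECG biometric identification and authentication

`ecgid` implements a complete electrocardiogram (ECG) biometric pipeline for
researchers studying physiological-signal identity recognition: given
single-channel ECG records from a cohort of enrolled subjects, it answers
*who produced this signal* (identification, a one-to-many decision) and *does
this signal belong to the claimed identity* (authentication, a one-to-one
threshold decision).

Two interchangeable similarity-score generators feed one classifier:

* **Recurrent path.** One next-sample predictor per enrolled subject: an
  embedding over `SD = 512` quantized amplitude levels, three stacked GRU
  layers, and a dense softmax head whose expectation `ŷ_n = Σ_k k·P(k)`
  predicts the next sample. The window prediction error
  `e = (1/W) Σ_n (ŷ_n − y_n)²` (with `y_n` the input shifted by one sample)
  is low on the subject the model was trained on and high on everyone else;
  scores are `S(p,i,w) = e(p,i,w) / max_p' e(p',i,w)`.
* **Convolutional path.** A two-stream dilated temporal convolutional
  classifier: one stream sees the whole preprocessed window (non-fiducial),
  the other an R-peak-centered single-cycle sub-segment (fiducial, two fewer
  blocks). Each block is a dilated 1-D convolution (24 kernels of size 4),
  batch norm, and ReLU; streams end in 256-unit and per-subject logit layers,
  are trained independently (Adam, cross-entropy), and are fused by the sum
  rule. Scores are `S(p,i,w) = 1 − o(p)/max(o)` on the softmaxed fused output.

Both score tensors go through the **Relative Score Threshold Classifier**:
batches of `B` consecutive windows are collapsed by the minimum
`S̃(p,i,b) = min_w S(p,i,w)`, normalized per predictor
`S̄ = (S̃ − min_p S̃)/(max_p S̃ − min_p S̃)`, and decided by
`argmin_p S̄` (identification) or `S̄(p,·,·) ≤ δ` (authentication).
Evaluation reports accuracy/specificity/sensitivity, per-individual ROC
curves with the equal error rate (EER) at the FNR = FPR crossing, and sweeps
of both against batch size.

A synthetic multi-subject ECG generator (Gaussian-bump PQRST morphology,
per-subject heart rate, RR jitter, baseline wander, noise, and optional
cross-session morphology drift) provides a fully self-contained test bed
with ground-truth R-peak locations.

The neural networks are implemented directly in numpy with hand-derived
backpropagation (gradient-checked against finite differences in the test
suite), so the package has no deep-learning framework dependency.

## Worked example

```python
from ecgid import (CohortSpec, make_cohort, PreprocessConfig, build_windows,
                   SplitSpec, split_train_test, TwoStreamTCNN, batch_sweep)

records, truth = make_cohort(CohortSpec(n_subjects=5, duration=240, fs=250, seed=1))
cfg = PreprocessConfig.for_fs(250, window=256, overlap=0.67)
windows = build_windows(records, cfg, path="tcnn")
train, test = split_train_test(windows, SplitSpec(train_fraction=0.33))

model = TwoStreamTCNN(n_layers_nonfid=5, epochs=15, seed=1).fit(train)
scores = model.score_tensor(test)
report = batch_sweep(scores, [1, 10], fs=250, W=256, overlap=0.67)
for B, entry in report.sweep.items():
    print(f"B={B:3d}  {entry['seconds']:6.1f} s/batch  "
          f"accuracy={entry['accuracy']:.4f}  EER={entry['eer_mean']:.4f}")
```

prints

```
B=  1     1.0 s/batch  accuracy=0.9983  EER=0.0000
B= 10     4.1 s/batch  accuracy=1.0000  EER=0.0000
```

i.e. single windows (about one second of signal) already identify the right
subject almost always, and aggregating ten consecutive windows with the
batch-minimum rule removes the remaining errors and drives the
authentication equal error rate to zero on this clean synthetic cohort.

The same pipeline is scriptable from a shell via the `ecgid` console command
(`synth`, `preprocess`, `train-rnn`, `train-tcnn`, `score`, `evaluate`).

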