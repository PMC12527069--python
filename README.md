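# ecgkit

Heartbeat classification for the five AAMI arrhythmia classes — **N**
(normal), **S** (supraventricular ectopic), **V** (ventricular ectopic),
**F** (fusion) and **Q** (unclassifiable/paced) — from single-lead ECG at
360 Hz. The package is aimed at researchers who want a fully reproducible,
dependency-light reference pipeline: every stage from raw annotated signal
to per-class evaluation report is seeded, tested, and runnable without any
data download thanks to a built-in synthetic ECG generator.

## What it implements

**Preprocessing.** R-peak detection (annotation-guided, or a
Pan–Tompkins-style detector with band-pass 5–15 Hz, derivative, squaring,
moving-window integration and two-level adaptive thresholding with
searchback), fixed-window beat segmentation around each R peak (default
280 samples, peak at index 99), per-beat z-scoring, probabilistic
subsampling of the dominant normal class (each N beat kept with
probability 0.15), removal of non-finite segments, and wavelet denoising:
a 3-level Symlet-5 DWT with the universal hard threshold

&nbsp;&nbsp;&nbsp;&nbsp;σ = median(|c<sub>D1</sub>|) / 0.6745,&nbsp;&nbsp;
λ = σ √(2 ln n),

where c<sub>D1</sub> are the finest detail coefficients and n the segment
length; detail coefficients with |c| ≤ λ are zeroed, approximation
coefficients pass through.

**Models.** Three classifiers over beat segments, built on a small NumPy
neural-network engine written for this package (1-D convolution, max
pooling, dropout, dense and LSTM layers with full backpropagation through
time, He-normal initialization, Adam/AdamW, weighted cross-entropy):

* a 1-D CNN — Conv(1→256, k=8, s=5) and Conv(256→128, k=7, s=4) blocks,
  each with ReLU/dropout/max-pool, then a 128-unit dense layer and a
  5-class softmax;
* a stacked LSTM — 64→32→16 units with 0.4 inter-layer dropout, the
  standard four-gate cell
  (i, f, o gates and candidate state, c<sub>t</sub> = f⊙c<sub>t−1</sub> +
  i⊙g, h<sub>t</sub> = o⊙tanh c<sub>t</sub>);
* the hybrid 1D-CNN–LSTM — the CNN front end's final feature map handed to
  a single LSTM layer as a (time × channels) sequence, then a dense
  softmax head (281,541 parameters at the defaults).

Class imbalance is countered twice: by the subsampling step above and by
weighted cross-entropy with inverse-class-frequency weights.

**Hyperparameter search.** A from-scratch Grey Wolf Optimizer: candidate
hyperparameter vectors (filter count, kernel size, stride, LSTM units,
dropout; optionally learning rate and batch size) are wolves whose
positions are pulled toward the three best solutions (α, β, δ) through the
encircling equations, with the exploration control *a* decreasing linearly
from 2 to 0. Fitness is the validation accuracy of the candidate hybrid
model trained under a reduced epoch budget; the winner is retrained at
full budget.

**Evaluation.** Confusion matrices and one-vs-rest precision/recall/F1
per class with macro and support-weighted averages; overall accuracy is
trace/total, and support-weighted recall equals it by construction.

## Worked example

```python
from ecgkit import (SyntheticSpec, generate_beat_dataset, stratified_split,
                    HybridCNNLSTM, TrainConfig)
from ecgkit.preprocess import zscore_dataset, denoise_dataset
from ecgkit.evaluate import render_report

spec = SyntheticSpec(n_beats=1000, noise_sd=0.35, seed=3)
ds = denoise_dataset(zscore_dataset(generate_beat_dataset(spec)))
train, test = stratified_split(ds, 0.8, seed=1)

result = HybridCNNLSTM(train, test).fit(
    TrainConfig(epochs=5, batch_size=20, learning_rate=1e-3,
                optimizer_name="adamw", seed=0))
print(result.summary())
print(render_report(result.evaluate(test))[0])
```

prints

```
HybridCNNLSTM training results
============================================
epochs                    5
batch size               20
optimizer             adamw
learning rate         0.001
seed                      0
parameters           281541
--------------------------------------------
final train acc      0.9087
final val acc        0.8850
best val acc         0.9700 (epoch 1)
       metric   N   S    V   F    Q  average
precision (%)  98  79  100   5  100       76
   recall (%)  85  92  100  50  100       85
       f1 (%)  91  85  100  10  100       77
overall accuracy (%): 89
```

The 1,000 beats follow the MIT-BIH-like class mixture (about two thirds
N, under 2% F), corrupted with heavy white noise (SD 0.35 mV) and baseline
wander. After denoising, five epochs of the hybrid model reach 89% held-out
accuracy; the table shows the familiar failure mode of imbalanced ECG
classification — the 12-beat fusion class F is the weakest row, while the
morphologically distinctive V and Q classes are perfect. At the package's
default noise level (0.05 mV) the same pipeline separates all five classes
completely.

The same workflow is available from the shell:

```bash
ecgkit simulate --record --n-beats 200 --out run/rec
ecgkit preprocess --record run/rec --out run/beats.csv
ecgkit train --model hybrid --data run/beats.csv --epochs 10 --out run/ckpt
ecgkit evaluate --checkpoint run/ckpt --data run/beats.csv --out run/report
```

or end to end from one YAML config with `ecgkit run --config cfg.yaml`,
where a single global seed reproduces the whole run (each stage writes a
manifest with its derived seed, parameters and output digests).

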