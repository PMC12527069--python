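# Methods

This note records the scientific and numerical choices behind ecgkit: the
models and their assumptions, the synthetic data the tests rely on, and
the places where the design was genuinely open.

## Synthetic ECG generator

The generator emulates single-lead 360 Hz recordings with one beat
archetype per AAMI class. Each archetype is a sum of Gaussian deflections
standing in for the P wave, the QRS complex (R deflection with Q and S
dips whose widths scale together) and the T wave:

| class | P wave | QRS width | R amplitude | T wave | extra |
|---|---|---|---|---|---|
| N | 0.15 mV | 1× | 1.00 mV | +0.30 mV | — |
| S | absent | 1× | 0.90 mV | +0.40 mV | — |
| V | absent | 3× | 1.30 mV | −0.45 mV (discordant) | — |
| F | 0.08 mV | 2× | 0.65 mV | +0.18 mV | — |
| Q | absent | 4× | 0.45 mV | +0.05 mV | 0.70 mV pacing spike |

The Q archetype carries a narrow (σ = 4 ms) stimulus-artifact spike at the
R position because paced beats dominate that class in ambulatory Holter
databases; a purely broad low-amplitude complex would misrepresent the
class and is also nearly invisible to any energy-based QRS detector,
which real paced beats are not. All five archetypes are pairwise
distinguishable (zero-lag correlation after z-scoring < 0.95; the largest
observed pair is N–S at ≈ 0.89).

Records are the concatenation of per-beat templates at a fixed heart
rate, corrupted by additive white Gaussian noise (default SD 0.05 mV) and
a sinusoidal baseline wander (default 0.05 mV at 0.3 Hz with random
phase) — the two dominant artifact families in ambulatory ECG. The
default class mixture is the five-class beat census of the MIT-BIH
database taken as fractions, (0.667, 0.058, 0.164, 0.019, 0.092), so the
severe majority-N imbalance is reproduced. Beat-matrix generation uses
the same archetypes with a default 280-sample window (R peak at index
99 ≈ 0.275 s pre / 0.5 s post at 360 Hz; the window covers P through T at
normal rates and is configurable).

What the generator does **not** emulate: beat-to-beat morphology
variability within a class, RR-interval variability and rhythm context
(every beat is equally spaced), electrode-motion artifacts, multi-lead
geometry, and intermediate or patient-specific morphologies. Passing
tests on this data therefore demonstrate that the pipeline and models are
implemented correctly and can exploit morphological separations of the
magnitude the archetypes provide; they do not certify clinical
performance on real recordings, where class overlap is far greater.

## Preprocessing

* **R-peak detection.** With annotations available, each annotated index
  is refined to the local signal maximum within ±0.05 s. Without
  annotations, a Pan–Tompkins-style chain runs: Butterworth band-pass
  5–15 Hz (order 2, zero-phase), derivative, squaring, 150 ms
  moving-window integration, then two-level adaptive thresholding:
  running signal and noise peak estimates (SPKI/NPKI, exponential updates
  0.125) set THR1 = NPKI + 0.25(SPKI − NPKI), a 0.2 s refractory period
  separates accepted peaks, and when the gap since the last beat exceeds
  1.66× the running 8-beat RR average the interval is re-searched at a
  lower threshold. Measured sensitivity on synthetic records at noise SD
  0.05 is ≥ 0.97 across seeds with no false positives.
* **Segmentation** cuts pre+1+post samples around each peak; windows
  overrunning the record are dropped and counted. Labels come from the
  nearest annotation within half a window via the AAMI consolidation
  (N←{N,L,R,e,j}, S←{A,a,J,S}, V←{V,E}, F←{F}, Q←{/,f,Q}; everything else
  excluded).
* **Normalization** is per-segment z-scoring with the population SD;
  constant segments map to zeros. z-scoring is idempotent.
* **Majority subsampling** retains each normal beat with an independent
  Bernoulli draw (default keep probability 0.15) and never touches other
  classes; survivor order is preserved.
* **Denoising** applies a 3-level Symlet-5 DWT with symmetric signal
  extension (the reconstruction depends on the extension mode; symmetric
  keeps boundary error negligible). The noise scale is Donoho's estimate
  σ = median(|cd|)/0.6745 from the **finest** detail band — the standard
  choice, since coarser bands carry signal energy — and the universal
  threshold λ = σ√(2 ln n) uses the segment length for n. Hard
  thresholding zeroes detail coefficients with |c| ≤ λ (ties zeroed) at
  **all** levels with the single λ; approximation coefficients are never
  touched. Denoising runs per segment after normalization; whole-record
  denoising is available by calling `denoise_dwt` on the record signal.
  The estimator reading of "MAD" is the median absolute coefficient (the
  0.6745 normalizer only makes sense for that estimator), not the
  median-absolute-deviation-from-median.

## Classifiers

The three architectures and their published training regimens:

| model | architecture | optimizer | lr | batch | epochs |
|---|---|---|---|---|---|
| 1D-CNN | Conv(1→256,k8,s5,p1)+ReLU+Drop .15+Pool2; Conv(256→128,k7,s4,p1)+ReLU+Drop .10+Pool2; Flatten; Dense 128+ReLU; Dense 5 | Adam | 1.5e-4 | 20 | 30 |
| LSTM | stacked 1→64→32→16, dropout 0.4 between layers, dense head on last hidden state | Adam | 2e-4 | 20 | 30 |
| hybrid | CNN front end → (time × channels) sequence → LSTM(64) → dense head | AdamW | 1e-3 | 20 | 30 |

The hybrid hand-off deliberately keeps the conv feature map as a sequence
(6 time steps × 128 channels at the defaults) rather than flattening to a
single step, so the recurrent stage has a temporal axis to model. At the
defaults the hybrid has 281,541 trainable parameters.

The engine is NumPy throughout: im2col convolutions, full BPTT for the
LSTM (fused i,f,g,o gate order), inverted dropout, He-normal
initialization (SD = √(2/fan_in), biases zero; for the LSTM the input and
recurrent blocks use their own fan-in), and Adam/AdamW (decoupled decay
0.01 applied to weight matrices only). The per-equation LSTM cell in
`ecgkit.nn.cell` shares no code with the batched layer and serves as the
second route in equivalence tests (agreement ≤ 1e-5 over random
trajectories; observed ≈ 1e-16).

The loss is weighted cross-entropy, Σᵢ w_{yᵢ}(−log pᵢ[yᵢ]) / Σᵢ w_{yᵢ},
with inverse-class-frequency weights by default; uniform weights reduce
it exactly to plain cross-entropy. Probabilities at the true label are
clamped at 1e-12 with a warning. Training is deterministic given the
seed: initialization, dropout masks and shuffling all derive from it.
A learning rate of zero provably leaves weights at their initialization.

An LSTM batch size of 16 is equally defensible (both 16 and 20 appear in
the source regimens); 20 is the default and the value is configurable.

## Grey Wolf Optimizer

Positions live in a continuous box; integer dimensions decode by
clip-then-round (half up, documented tie rule). One update draws fresh
r₁, r₂ per leader and dimension, computes A = 2a·r₁ − a, C = 2r₂,
D = |C·X_leader − X| and X_k = X_leader − A·D for the three leaders, and
moves the wolf to their mean, clipped to bounds (clipping, not
reflection, for reproducibility). The control scalar follows
a(t) = 2(1 − t/n_iters), so a(0) = 2 and a(n_iters) = 0 exactly.
Leaders are ranked with stable index tie-breaking. Elitism is tracked
explicitly: the best-ever position is recorded separately from the
per-iteration α, and its fitness is non-decreasing by construction. A
raising fitness function scores −∞ and the search continues; repeated
decoded positions are cached, bounding evaluations at
n_wolves·(n_iters+1).

The default search space is filters [8, 320], kernel [3, 7], stride
[2, 8], LSTM units [20, 256], dropout [0.001, 0.6] (integers except
dropout); an extended space optionally adds a log-uniform learning rate
[1e-4, 3e-3] and a batch-size choice {16, 20, 32}. The searched filter
count sets the first conv block, the second gets half (minimum 8).
Candidate fitness is validation accuracy after a reduced training budget
(default 5 epochs) — the per-candidate budget is an open choice, and a
short budget is what makes a 200-evaluation search tractable; the winner
is retrained at the full 30 epochs. Infeasible architectures (strides
that exhaust the input) score 0 rather than aborting.

On the 3-D sphere benchmark (bounds ±5, 10 wolves, 50 iterations) the
pack reaches the optimum to ≈ 1e-8 in every tested seed, and the
population spread contracts in the late, exploitative iterations.

## Evaluation

Overall accuracy is trace/total — the only multiclass reading consistent
with the one-vs-rest binary form, with which it coincides class by class.
Undefined precision or recall (empty denominator) reports 0 with a
warning. "Average" rows in rendered tables are unweighted macro means;
support-weighted recall is also exposed and equals overall accuracy
identically. Rendered percentages round half-up to integers.

## Scaled-down study sizes

The self-contained study the acceptance script runs uses 2,000 synthetic
beats (balanced five-class mixture, noise SD 0.05) with an 80/20
stratified split, 10 hybrid training epochs, and a 3-wolf / 3-iteration
search whose candidates train 2 epochs on a 600-beat stratified subset —
sizes chosen so the whole study completes in minutes on one CPU while
still exercising every pipeline stage end to end. Under these conditions
the hybrid model separates the archetypes essentially perfectly
(≥ 90% required, ~100% observed), which is the expected behaviour for
morphologies this distinct; the number is a correctness check of the
pipeline, not a claim about MIT-BIH-scale difficulty.

## Known limitations

* The synthetic archetypes understate real intra-class variability; see
  above for what that implies about test evidence.
* The stratified split uses floor + largest-remainder allocation; other
  rounding conventions give per-class counts differing by one beat.
* The unannotated R-peak detector is tuned for single-lead morphologies
  like the generator's; heavily pathological rhythms (e.g. ventricular
  flutter) are out of scope.
* Training determinism holds within a NumPy/BLAS installation; exact
  bit-reproducibility across BLAS builds is not guaranteed, though all
  documented checks use tolerances that absorb this.
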