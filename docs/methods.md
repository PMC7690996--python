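# Methods

## Problem and model

The package classifies single-trial fixation-related potentials (FRPs):
EEG epochs time-locked to self-generated eye-fixation onsets during a
guided visual search, where rare fixations on a target letter elicit a
sustained positive P300-like component (~250–500 ms, centroparietal
maximum) and the remaining ~88% of fixations do not. Single trials are
dominated by background EEG, so the classifier combines a learned
first-order stage with a second-order (covariance) stage:

1. **CONV-Net.** The first block of EEGNet-8,2 — 8 temporal filters of
   length 64 samples followed by 2 depthwise spatial filters per
   temporal filter over C = 19 electrodes — acts as a bank of learned
   frequency-specific spatial filters. The full three-block EEGNet is
   trained end-to-end (class-weighted cross-entropy, Adam, validation
   stopping) but only to obtain this block; the feature map per trial
   is the block-1 post-ELU activation taken **before** average pooling,
   X ∈ ℝ^{D×N} with D = 16 and N = 128 time instances. Taking the tap
   before pooling is deliberate: pooling would shrink N below 128 and
   blur the temporal structure the next stage depends on.
2. **ACOVP.** Each row-centered feature map X̄ is stacked under the
   row-centered target template X̄_tar (the mean feature map of
   training-fold target trials) and pooled to the joint sample
   covariance AugC = X̃X̃ᵀ/(N−1) ∈ ℝ^{32×32}, X̃ = [X̄_tar; X̄].
   Plain covariance is invariant to any permutation of the N time
   columns; the trial–template cross block is not, so the augmented
   matrix encodes temporal ordering while inheriting the covariance
   representation's tolerance to latency shifts. A trace-scaled ridge
   AugC + λ·tr(AugC)·I (λ = 1e−5) enforces strict positive
   definiteness.
3. **SPDC-Net.** A Riemannian network on the SPD manifold: two
   BiMap+ReEig blocks without dimension reduction
   (B = WᵀXW with semiorthogonal W; X′ = U max(Λ, εI) Uᵀ), a LogEig
   layer (U log(Λ) Uᵀ), row-major flattening to 1024 features, and a
   class-weighted softmax. BiMap weights are optimized by Riemannian
   SGD on the compact Stiefel manifold: the Euclidean gradient is
   projected to the tangent space (canonical metric,
   ξ = G − W·sym(WᵀG)) and the step retracted by QR factorization with
   sign-fixed R diagonal.

The two stages are trained independently (no joint fine-tuning): the
covariance pooling in between is not parameterized, and independent
training keeps the template a fixed, label-derived statistic.

## Hand-derived backpropagation

Both networks are implemented in NumPy with explicit gradients.
Backpropagation through the eigendecomposition (ReEig, LogEig) uses the
Daleckii–Krein/Löwner form: for a spectral map f(X) = U g(Λ) Uᵀ with
upstream gradient G,

    ∂L/∂X = U (Γ ∘ (Uᵀ sym(G) U)) Uᵀ,
    Γ_ij = (g(λ_i) − g(λ_j)) / (λ_i − λ_j),  Γ_ii = g′(λ_i).

Pairwise eigenvalue differences in the denominator are clamped at
1e−10 in magnitude; repeated eigenvalues occur at initialization on
near-isotropic inputs and the clamp keeps the gradient finite there.
Correctness is pinned by a central finite-difference suite (d = 5 toys,
10 seeds, relative error < 1e−4; observed ≈ 1e−9).

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| temporal filters F1 / spatial S1 | 8 / 2 | — | EEGNet-8,2 configuration |
| temporal kernel | 64 | samples | half the 128 Hz epoch (0.5 s) |
| dropout | 0.25 | — | applied after each pooling stage |
| training epochs (both nets) | 100 | — | with validation stopping and best-weight restore |
| validation fraction | 0.2 | — | random, seeded split of each training fold |
| class weights | majority = 1, minority = majority/minority counts | — | inverse-proportion weighting for the ~1:8 imbalance |
| Adam learning rate (CONV-Net) | 1e−3 | — | standard default |
| batch size CONV-Net / SPDC-Net | 64 / 32 | trials | unspecified upstream; exposed in config |
| ReEig floor ε | 1e−4 | — | reference SPDNet convention |
| Riemannian SGD learning rate | 1e−2 | — | stable on 32×32 inputs |
| covariance ridge λ | 1e−5 | — | applied unconditionally; negligible when N > 2D, needed only for rank-deficient pooling |
| batch-norm momentum | 0.9 | — | running statistics converge within the short training runs used here |

CONV-Net computation is float32; SPDC-Net is float64 (eigensolver
accuracy dominates the gradient-check tolerance).

## Synthetic data generator

The generator emulates the statistical structure the pipeline is
sensitive to, not the biophysics:

- **Waveform.** A half-period raised-cosine positivity (amplitude 5 μV,
  width 300 ms, latency 400 ± 30 ms Gaussian, truncated to keep the
  pulse inside the epoch), scaled per channel by a fixed topography
  that is maximal at Cz/CPz/Pz. Only target trials receive the pulse.
- **Noise.** Spatially mixed 1/f-amplitude (pink) noise, per-channel SD
  10 μV by default (AR(1) alternative). The mixing matrix is a fixed
  structural constant so inter-channel correlation is realistic but
  reproducible. At the defaults the single-trial peak SNR is low
  enough that a naive template matcher stays clearly below ceiling,
  keeping the benchmark non-degenerate.
- **Labels.** Exactly round(n × target_rate) targets at randomized
  positions, target_rate = 0.12 (3 targets among 25 letters).
- **Sessions.** Continuous 1000 Hz EEG with embedded responses at
  fixation onsets, and a gaze trace alternating 40 ms saccades between
  5×5 grid positions (≈100°/s) with long (>350 ms) fixations whose
  drift stays below 0.1° dispersion.

Not emulated: ocular/blink artifacts (hence the ICA stage is a logged
no-op), volume-conduction head models, letter rendering, overlapping
responses from consecutive fixations, and non-stationarities across
blocks. Passing tests therefore demonstrate that the pipeline recovers
the structure it claims to exploit (topography, latency jitter,
temporal ordering, class imbalance) — not performance on recorded EEG.

## Preprocessing chain

Fixation detection thresholds velocity (30°/s) and acceleration
(8000°/s²) on a 5-sample moving-average-smoothed gaze trace (central
differences), then splits candidate runs wherever the spatial excursion
since fixation start reaches 0.15°. Validation keeps the first fixation
per trial landing within 3° of the guiding circle and lasting longer
than 350 ms. The EEG chain is: order-2 zero-phase Butterworth 1–40 Hz
(filtfilt, so the effective magnitude response is |H|²); epochs −200 to
+1000 ms (closed/half-open, 1200 samples at 1 kHz) aligned to the
detected fixation onset; baseline subtraction over −200…−100 ms
(the pre-onset-only reading of the baseline window — the alternative
−200…+100 ms is one config flag away); peak-to-peak rejection of
epochs whose any-channel max−min strictly exceeds 100 μV in any 50 ms
window slid by 25 ms (final partial window included; *strictly*,
because the criterion is "surpassing" the threshold); polyphase 16/125
resampling of the (0, 1000) ms window to exactly 128 samples.

## Evaluation protocol

Chronological 5-fold CV with preserved class ratio, realized as
per-class contiguous segmentation: each class's chronologically ordered
trials are cut into 5 contiguous segments and fold j tests on segment j
of both classes. This satisfies temporal contiguity and ratio
preservation (within one trial) simultaneously. A seeded random 20% of
each training fold is the validation set (re-drawn per fold, seeded as
seed + fold index). Scores are rank-based AUC; the across-fold spread
uses the sample (n−1) standard deviation. Reduced-set experiments
subsample each class without replacement (round(fraction × class
count)), preserving chronological order of survivors; at fraction 1.0
one repeat equals the full-set run exactly.

Ablations (plain covariance pooling; block-2 tap) reuse the identical
trained CONV-Net within each fold so the comparison isolates the
substituted component; the identity ablation is the same code path as
the main pipeline.

Leakage control: the target template and all trained parameters of a
fold are functions of that fold's training indices only; the template
is computed from the full training fold (fit + validation trials — the
validation split exists for early stopping, not for holding out
labels) and frozen before any test trial is transformed.

## Problem sizes for the shipped benchmarks

The default test suite and the acceptance script run the end-to-end
benchmark at 400 trials (12% targets), CONV-Net 8 epochs and SPDC-Net
30 epochs with validation stopping, 5-fold CV: on strongly separable
data these short schedules already saturate (mean AUC ≈ 1.0), so the
benchmark measures pipeline correctness rather than optimization
budget. The high-SNR condition is noise SD 2 μV; the
pooling-comparison condition is noise SD 10 μV with 40 ms latency
jitter, where template augmentation shows its advantage over plain
covariance pooling. All defaults remain at their stated values
(100 epochs etc.) for users running the full protocol.

## Numerical choices and degenerate inputs

- Temporal convolutions use same-length zero padding (left (k−1)//2) so
  N = T = 128; convolutions are FFT-based.
- ReEig uses the subgradient 1{λ > ε} at the clamp point; LogEig
  refuses non-PD inputs rather than clamping silently.
- QR retraction fixes the sign of the R diagonal, making the
  factorization (and hence training) deterministic.
- An all-constant trial is zero after row centering; its pooled
  covariance cannot be made PD by trace-scaled loading and is rejected
  with an error instead of passing a singular matrix downstream.
- Epoch onsets too close to a recording edge are dropped with a logged
  warning rather than zero-padded.
- All randomness (generator, initializations, batch order, dropout,
  splits) derives from explicit integer seeds; derived seeds are
  produced by `numpy.random.SeedSequence` and kept below 2^31.

## Known limitations

- The CNN is NumPy on CPU; it is adequate for the trial counts here
  (hundreds to a few thousand) but not for large-scale training.
- Only binary classification and a single target template are
  supported (no multi-class templates, no shrinkage estimators beyond
  trace-scaled loading).
- The fixation parser implements a standard
  velocity/acceleration/dispersion scheme; vendor parsers differ in
  merging heuristics, so onsets on real eye-tracking data may deviate
  by a few samples.
- Statistical comparison machinery (Friedman tests, post-hoc
  corrections) is out of scope; results are exported as tidy CSV for
  external analysis.
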