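# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open. It states nothing
that the test suite or `scripts/acceptance.py` does not itself compute.

## Architecture

The classifier maps a window `x ∈ R^{T×C}` (T = 128, C = 9 for the UCI HAR
geometry; T = 151, C = 3 for UniMiB SHAR) to class probabilities through:

1. **TCN block(s).** One block is a ladder of residual levels, one per
   dilation rate d ∈ {1, 2, 4, 8}. A level computes

       main(x)  = drop(BN(conv_d(ReLU(drop(BN(conv_d(x)))))))
       level(x) = ReLU(main(x) + conv_{1×1}(x))

   where `conv_d` is a bias-free dilated convolution (kernel k, F filters)
   with causal left zero-padding of (k−1)·d, so time length is preserved
   and output at time t depends only on inputs at ≤ t. Both convolutions
   in a level share the level's dilation. Blocks after the first receive
   F-channel input, so their levels all have the shape of levels 2..D.
2. **Non-overlapping max pooling** of width 4 (floor division of the
   sequence length: 128 → 32, 151 → 37), then a bias-free **bridge 1×1
   convolution** + batch-norm + ReLU.
3. **GRU stack**: n = 2 layers of u = 128 units returning full sequences,
   one batch-norm between consecutive layers (n−1 norms; none before the
   first or after the last). Bidirectional variants run each layer in both
   directions and concatenate, doubling the width seen by the next layer,
   the inter-layer norms, and the head.
4. **Global average pooling** over time and a dense softmax head trained
   with categorical cross-entropy (mean over samples).

## Parameter accounting

Counts include non-trainable batch-norm moving statistics (4 per channel in
total: scale, shift, moving mean, moving variance). Closed form, with D
dilation levels and B blocks:

    block 1   = [kCF + kF² + 8F + CF] + (D−1)·[2kF² + 8F + F²]
    block ≥ 2 = D·[2kF² + 8F + F²]
    bridge    = F² + 4F
    GRU layer = 3·(i·u + u² + 2u) per direction, input width i
    inter-GRU norm = 4 · output width
    head      = width·m + m

The built network's allocated arrays sum to the same totals; the test suite
pins both routes to the published figures on every ablation axis, plus the
implied regularities (adding a block always costs 4·5376 = 21504 for the
UCI settings; the total as a function of GRU width is 9u² + 118u + 20454).

Three choices here are forced by the totals rather than stated anywhere
explicitly, and we adopt them as the only consistent assignment:

- the residual merge is element-wise **addition** (concatenation would
  double channel counts and contradict every total);
- all convolutions are **bias-free** (each is followed by a batch-norm, or
  is a linear shortcut), and the bridge conv has its own batch-norm;
- GRU gates use the **double-bias** parameterisation (6u bias parameters
  per layer). The textbook single-bias form is available in the oracle
  behind `double_bias=False` for equation-level tests, but is not what the
  counts describe.

Two orderings are parameter-neutral and were fixed by convention: the
sub-unit order conv → BN → dropout → ReLU, with the level's residual add
taking the second sub-unit's dropout output and the final ReLU applied
after the merge; and both convolutions of a level using that level's
dilation.

## Engine and oracle

The layer engine is a float64 NumPy implementation with hand-written
backward passes (verified against central finite differences to ~1e-6
relative error in the tests). The oracle module re-implements every
forward operation as a literal per-timestep/per-tap loop and replays a
built network from its exported weights; engine and oracle must agree
within 1e-4 per class probability (they agree to ~1e-15 in practice, since
both run in double precision). Batch-norm in inference and in the oracle
uses stored moving statistics (momentum 0.99, ε = 1e-3), so comparisons
are deterministic; dropout is inference-disabled.

Numerical conventions: softmax with max-subtraction; probabilities clipped
to [1e-7, 1−1e-7] before logarithms; Adam with β₁ = 0.9, β₂ = 0.999,
ε = 1e-7; Glorot-uniform initial kernels, orthogonal recurrent kernels,
zero biases.

## Training protocol

Batch size 32, Adam at 1e-3, categorical cross-entropy, up to 100 epochs.
The learning rate is multiplied by 0.1 after 3 epochs without
validation-loss improvement and floored at 1e-4 — the factor is a
convention; with this initial rate and floor the schedule has exactly one
step, which is what the stated minimum implies. Weights are checkpointed
whenever validation loss improves (ties keep the earlier epoch), and
evaluation restores the best checkpoint. Validation is a seeded,
class-stratified 10% carve-out of the training portion. No class weights
and no early stopping (training runs its full epoch budget; the checkpoint
handles overfitting). Training is seeded and reproducible on a fixed BLAS
configuration.

## Evaluation

Accuracy plus macro-averaged precision/recall/F1 and a true-by-predicted
confusion matrix. Macro averaging is used because a single
precision/recall/F1 triple can then differ from accuracy on imbalanced
test sets, which is the behaviour the reference figures show (weighted
recall would equal accuracy exactly). Five-fold cross-validation is a
seeded random partition over windows (subject-dependent); because it is
unstated whether a published five-fold figure is a mean over folds or
pooled over windows, the cross-validation result reports both.

## Synthetic data

The generator produces fixed-length multi-channel windows with exact class
balance: per class a two-harmonic sinusoid (fundamental + 0.3× its first
overtone) with class-specific frequency, amplitude and constant offset,
per-window random phases, per-subject multiplicative jitter (σ = 0.05) on
amplitude and frequency, additive Gaussian noise (σ = 0.1), and a fixed
decaying per-channel gain. This is the simplest family giving each class a
distinct spectro-temporal signature analogous to gait periodicity, while
static postures differ mainly by a gravity-like offset. Two of the six
default classes (Sitting/Standing) have near-identical offsets and small
amplitudes, so the classic static-posture confusability exists in
miniature; all six fundamental frequencies are distinct, and the defaults
keep noise within the separable regime noise_sd ≤ 0.3·min(amp).

What passing the recovery test shows — and does not show: a network trained
15 epochs on the default corpus (30 subjects, 21/9 subject-independent
split, 1800 windows) recovers held-out-subject labels at ≥ 90% while a
label-shuffled control stays at chance (1/6 ± 5 points). The control is
scored at the final epoch rather than at the best-validation checkpoint:
with shuffled labels the validation loss only worsens as training
proceeds, so checkpoint selection degenerates to the near-initial network
and would measure the random initialisation's alignment with the input
clusters instead of what training extracted. This validates
the pipeline (gradients, schedule, checkpointing, protocol plumbing) and
the generator's class structure. It does not certify accuracy on real
inertial data: real signals are non-stationary, non-sinusoidal, contain
transitions and sensor artefacts, and real inter-subject variation is far
richer than multiplicative jitter.

## Problem sizes

Unit and property tests run on reduced geometries (windows of 12–128
steps, 2–8 filters, 4–12 GRU units) chosen to exercise every code path;
the recovery test and the worked example run the full standard
configuration on the default 1800-window synthetic corpus for 15 epochs,
which is sufficient for convergence on this corpus (validation accuracy
plateaus near 1 around epoch 11). The acceptance script involves no
training: its quantities are exact parameter totals of fully allocated
networks.

## Known limitations

- CPU-only and NumPy-based: throughput is adequate for the synthetic
  corpus and the public datasets, but far from a GPU framework.
- The Lea-style and Bai-style baseline presets are architectural skeletons
  for benchmarking plumbing, not faithful reproductions of those models'
  every detail (their published parameter totals depend on unstated
  choices).
- Determinism of training histories assumes a fixed BLAS thread
  configuration; different BLAS builds may differ in the last bits.
- The UCI HAR loader consumes the pre-windowed release; raw-signal
  preprocessing (gravity separation, filtering) is out of scope.
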