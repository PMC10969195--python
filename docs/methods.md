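# Methods

## The model

`sttcnn` implements a dual-branch transformer/CNN classifier for segmented
multichannel EEG. A segment is a channels × samples matrix `X` (3 s windows by
default: 600 samples at 200 Hz for SEED-like recordings, 384 at 128 Hz for
DEAP-like ones). The same matrix enters the network in two arrangements:

* **spatial branch** — tokens are channels; token features are the window's
  time course. Self-attention ranges over electrode positions, so attention
  scores are inner products between channel time courses (cross-channel
  similarity).
* **temporal branch** — tokens are time points; token features are the
  instantaneous cross-channel pattern. Attention ranges over time, capturing
  lagged similarity between topographic patterns.

Each branch applies a learned linear embedding per token to `d_model`
dimensions, adds the sinusoidal positional encoding

    PE(pos, 2i)   = sin(pos / 10000^(2i/d)),
    PE(pos, 2i+1) = cos(pos / 10000^(2i/d)),

and runs `n_encoder_layers` transformer encoder blocks: multi-head
self-attention (`h` heads, scaled dot-product `softmax(QKᵀ/√d_k)·V`), then a
position-wise feed-forward net (`Linear → ReLU → Linear`), each sublayer with
a residual connection followed by layer normalisation (post-norm, ε = 1e-5).

The two token maps are concatenated along the token axis into a single
`(seq_s + seq_t) × d_model` map, treated as a one-channel image and aggregated
by the prediction head: two same-padded 3×3 convolutions with
`conv_channels` kernels and ReLU, one 2×2 max pool, a fully connected layer
and softmax.

Four variants form the ablation family: `st-tcnn` (full model), `st-t`
(both branches, map flattened straight into the FC layer — no CNN), `s-t`
and `t-t` (single branch plus CNN head).

### Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `d_model` | 64 | encoder width; the raw token widths (62, 32 channels) are not divisible by `h = 8`, so a learned projection is required and its width is a free choice |
| `h` | 8 | attention heads (reference setting) |
| `n_encoder_layers` | 1 | one block per branch, matching the reference block diagram; configurable |
| `ff_dim` | 4·`d_model` | original transformer convention |
| `dropout` | 0.3 | applied after attention, after the feed-forward sublayer and before the FC layer (the rate is a reference setting; the placement is ours) |
| `conv_channels` | 64 | kernels per conv layer (reference setting) |
| learning rate | 1e-4 | Adam (β₁ 0.9, β₂ 0.999), reference setting |
| batch size | 128 | reference setting |
| `l2_lambda` | 1e-4 | coefficient of the L2 penalty added to the cross-entropy loss; applied to weight matrices only (biases and layer-norm affine parameters exempt) |
| `k_folds` | 10 | stratified cross-validation folds |
| window | 3 s | segmentation window; non-overlapping, trailing partial window discarded |
| rating threshold | 5.0 | 1–9 self-ratings binarised by strict `> 5` (midpoint convention); quadrants coded LALV=0, LAHV=1, HALV=2, HAHV=3 |

### Numerical and design choices

* **Input scaling.** Raw microvolt magnitudes destabilise dot-product
  attention, so segments are z-scored per segment and channel before
  embedding (`input_standardize`, on by default).
* **Positional encoding.** The absolute sinusoidal tables above, added (not
  concatenated) after embedding. With PE disabled the spatial branch is
  exactly channel-permutation-equivariant; PE deliberately breaks that
  symmetry so electrode identity is available to attention.
* **Head geometry.** Same-padding convolutions and a single pool keep the FC
  input dimension well-defined for any channel count / window length; the
  `st-t` variant flattens the concatenated map directly.
* **Implementation.** The network, its gradients and Adam are implemented on
  NumPy arrays through a small reverse-mode autodiff module
  (`sttcnn.autodiff`); convolution and pooling run in a token-major layout
  with im2col-style index tables to avoid image-layout transposes. Gradients
  are verified against central differences in the test suite. Training runs
  in float32 (`TrainConfig.precision`); API-level operations default to
  float64.
* **Degenerate conventions.** Precision/recall/F1 are defined as 0 when their
  denominator is 0; a two-sample t-test with zero variance on both sides and
  unequal means is reported as an error rather than ±∞. Cross-entropy of
  uniform predictions equals ln(n_classes) exactly.
* **Cross-validation.** Stratified segment-level assignment reproduces the
  reference protocol (each subject's segments divided into ten parts).
  Segment-level splitting lets windows of one trial land on both sides of a
  fold boundary, which inflates absolute accuracy through temporal
  autocorrelation; a `group_by_trial` mode keeps trials intact for
  leakage-free estimates. Model comparisons use the unpaired pooled-variance
  Student t-test by default (consistent with the reference tables' degrees of
  freedom), with a paired option.

## The synthetic generator

`SyntheticSpec` draws class-conditional EEG-like trials:

* background: 1/f^α noise (α = 1.0, 15 µV RMS) plus white noise (5 µV SD) —
  a minimal model of resting EEG spectra;
* spatial cue: a 10 Hz carrier whose per-channel gain follows a smooth
  class-specific topographic bump; amplitude = `spatial_snr` × 10 µV;
* temporal cue: a class-specific canonical-band oscillation (6, 20, 30 Hz …)
  with flat topography and random per-channel phases; amplitude =
  `temporal_snr` × 10 µV.

Each class is thus identifiable from either axis alone (two redundant views),
`spatial_snr = 0` removes all between-class spatial structure and likewise
for `temporal_snr = 0`; with both zero the class-conditional distributions
coincide and any classifier sits at chance. Per-trial randomness (phases,
burst times, noise) derives from `SeedSequence(seed, spawn_key=(class,
trial))`, so trials are independent and bit-reproducible.

What the generator does **not** emulate: volume conduction / realistic lead
fields, inter-subject variability, artifacts (blinks, EMG), non-stationary
background spectra, or the actual class structure of affective EEG. Passing
tests on this data shows the architecture, optimisation and evaluation
machinery behave as specified — not that the model reaches any particular
accuracy on real recordings.

## Study conditions at desk scale

Training-based checks run at a reduced problem size chosen once for CPU
practicality and frozen in `sttcnn.benchmarks`: 8 channels, 64 Hz, 15 s
trials, 1 s windows, `d_model` 16, `h` 8, `conv_channels` 32, dropout 0.1,
Adam at 1e-3, 42 epochs, 3-fold cross-validation, 6 trials per class
(270 segments).

* **Overfit check** uses `spatial_snr = temporal_snr = 3` (strong, ~+6 dB):
  a 64-segment subset must reach 100% training accuracy within 100 epochs.
* **Null check** uses both SNRs = 0: held-out accuracy must stay inside the
  95% binomial interval around chance.
* **Ablation direction** uses both SNRs = 0.5 (≈ −10 dB effect-to-background
  power, a realistic event-related effect size): the regime where neither
  dual variant saturates and the fusion advantage of two views over one is
  measurable. The expected qualitative ordering, checked over three seeded
  replicates, is `st-tcnn ≥ st-t > max(s-t, t-t)`.
* **Single-cue checks** plant only one cue, strongly (SNR 3), and require
  the matching single-branch variant (`s-t` on spatial-only, `t-t` on
  temporal-only) to beat chance on a held-out fold — these legs test that a
  branch can learn its own cue, independently of the fusion regime.

A caveat worth stating plainly: at this scale the single-branch variants
are not information-limited — either arrangement contains the full data
matrix — so the ablation ordering reflects learnability under a fixed
optimisation budget, not an information gap. The ordering is accordingly a
statistical tendency across replicates (it is required to hold in at least
2 of 3), not a per-seed certainty, and the margins between the dual
variants and the best single branch are a few accuracy points.

## Known limitations

* Accuracies printed on real SEED/DEAP by the reference work are not
  reproducible here: they require the datasets and tens of per-subject
  training runs at full scale.
* The NumPy implementation is single-threaded and desk-scale; full-scale
  training (62 × 600 tokens, `d_model` 64) is functional but slow.
* Segment-level cross-validation (the faithful default) overstates absolute
  accuracy on temporally autocorrelated data; use `group_by_trial=True` for
  honest generalisation estimates.
* The EDF reader ingests data and geometry only; annotations, montages and
  physical-dimension edge cases beyond microvolts are out of scope.
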