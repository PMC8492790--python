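# Methods

## Problem setting

`mitransfer` decodes two-class motor imagery (left- vs right-hand) from
multichannel EEG and studies how much a compact convolutional network
benefits from cross-subject transfer when the target subject contributes
only 40 training trials.  The intended application regime is
rehabilitation BCI, where per-subject data are scarce and patient
recordings carry weaker, less stable sensorimotor rhythms than healthy
recordings.

## Preprocessing

Trials pass through a fixed chain: an 8–30 Hz Butterworth band-pass
(isolating the mu ~10 Hz and beta ~20 Hz rhythms whose event-related
desynchronization, ERD, carries the imagery information), then integer
decimation from the acquisition rate (1000 Hz) to 100 Hz.  The band-pass
is order 4 per pass and applied forward–backward by default (zero phase;
the effective magnitude response is the squared single-pass response).
The filter order and causality are package choices — exposed as
`FilterSpec(order=, zero_phase=)` — made to avoid phase distortion inside
3 s epochs.  Edge transients are limited by short even-reflection padding
(`min(3·order, T−1)` samples).  Decimation performs no extra anti-alias
filtering because the preceding band-pass already limits the signal to
30 Hz < 50 Hz Nyquist; a Welch-spectrum guard refuses to decimate signals
with more than 5% of power above the new Nyquist unless forced.

Epochs are cut at imagery-cue onset with zero offset and 3 s length.  The
exact reaction-time gap between cue and imagery onset is unknowable from a
schematic timeline, so offset is a parameter with default 0.

## Architecture

The classifier is a compact EEG CNN in the EEGNet family.  For a `(C, T)`
input (reshaped to one feature map):

| Block | Layer | Output |
|---|---|---|
| 1 | temporal conv, F1 filters, kernel (1, 64), linear | (F1, C, T) |
| 1 | batch norm | (F1, C, T) |
| 1 | depthwise spatial conv, D filters/map, kernel (C, 1), linear | (D·F1, 1, T) |
| 1 | batch norm, ELU, avg-pool (1, 4), dropout | (D·F1, 1, T/4) |
| 2 | separable conv (depthwise (1, 16) + pointwise), F2 maps | (F2, 1, T/4) |
| 2 | batch norm, ELU, avg-pool (1, 8), dropout | (F2, 1, T/32) |
| — | flatten, dense + softmax, max-norm 0.25 | N |

Defaults: F1 = 4, D = 2, F2 = 8, dropout p = 0.5, N = 2.  Pooling uses
floor division, so any T ≥ 32 is accepted.  Convolutions are bias-free
(each is immediately followed by batch norm, which absorbs shifts); the
dense layer has a bias.  Batch norm uses momentum 0.99 and eps 1e-3.  Only
the dense rows carry a max-norm bound (0.25), re-projected after every
optimizer step; no constraint is placed on the depthwise weights (a
deliberate divergence from the original EEGNet recipe, which bounds them
at 1.0 — the `dense_max_norm` field can be repurposed by users who want
otherwise).

The engine is pure NumPy: forward and hand-derived backward passes per
layer, verified against central finite differences in the test suite.  The
long temporal convolution is evaluated by FFT on a transform padded to at
least T+K−1 (exact, no circular aliasing); short kernels use direct
sliding-window contractions.

## Training

Adam (β₁ 0.9, β₂ 0.999, eps 1e-8), categorical cross-entropy, learning
rate 1e-4, 100 epochs, shuffled minibatches.  Batch size defaults to 4:
with the low learning rate and fixed epoch budget, a 40-trial training set
needs the resulting 1000 updates to converge (batch 16 leaves the model
underfit).  No validation split or early stopping — training is
epoch-count-terminated.

### Transfer protocols

* `EEGNet_0`: random re-initialization, no transfer (control).
* `EEGNet_1`: load pre-trained weights, freeze Block 1, retrain Block 2 +
  a re-initialized classifier head.
* `EEGNet_2`: freeze Blocks 1 and 2, retrain only the classifier head.

Freezing is strict: frozen parameters and the batch-norm running
statistics of frozen blocks are bitwise constant during fine-tuning.
Fine-tuning runs a reduced 30-epoch profile at the same learning rate
(`FINETUNE_EPOCHS`); the scratch protocol `EEGNet_0` keeps the full
100-epoch budget, since it has no pre-trained features to start from.  An
optional second "unfreeze-all" stage is not implemented: its schedule is
underdetermined, and the frozen-block contracts are the property under
study.

The pre-training corpus is the pooled trial set of the synthetic source
subjects (clinical pre-training corpora are not publicly available in this
setting).

## Synthetic data generator

Each subject is a continuous recording: per-channel 1/f^α background noise
(α = 1), plus mu (10 Hz) and beta (20 Hz) oscillations — amplitude-
modulated by a slow (≤1 Hz) positive envelope to mimic waxing/waning
rhythms — radiating from two lateral motor sources (C3/C4-like positions
on a simplified 1-D channel axis, Gaussian spatial spread σ = 2 channels).
ERD is modelled as what it is physiologically: multiplicative attenuation
(factor 1 − erd_depth, 0.2 s cosine ramps) of the *contralateral* source's
oscillations during the 3 s imagery window.  Power is split 2:1 between mu
and beta; `snr_db` fixes rhythm-to-background power at the source channel.
The timeline per trial is 4 s rest, cue, 3 s imagery, 2 s gap; 60 balanced
trials per subject in seeded random order; amplitudes scaled to ±50 µV so
16-bit EDF quantization is realistic.

Defaults (64 channels, 1000 Hz, erd_depth 0.6, snr 6 dB) define the "easy"
(healthy-like) profile.  The "hard" (patient-like) profile halves
erd_depth and subtracts 6 dB of SNR, reflecting the weaker and less stable
rhythms of injured cortex.  Per-subject jitter (±10% on erd_depth, ±1 dB)
creates cohort variability.  Not modelled: volume conduction through a
head model, eye-blink/EMG artifacts, electrode drift, non-stationarity
across a session.  Consequently, passing tests demonstrate that the
pipeline recovers lateralized band-power structure under realistic noise —
not that it reaches any particular accuracy on clinical recordings.

## Evaluation

Per subject: repeated random stratified 40/20 splits (default 10 repeats;
the repeated-split reading of "10 cross-validation", since 10-fold
partitioning is impossible with fixed 40/20 sizes).  Stratification keeps
the 30/30 class balance in both halves — unbalanced draws would confound
accuracy — and can be disabled by flag.  Baselines consume byte-identical
split sequences (paired design): common spatial patterns (3 filter pairs,
log-variance features, Ledoit–Wolf-regularized covariances) feeding a
linear SVM (C = 1) or LDA; a plain per-channel log-variance feature is
available as a fallback.  The feature choice is an assumption — CSP is the
standard motor-imagery baseline — not something the comparison protocol
fixes.

Cross-subject aggregation weights subjects equally (grand mean = mean of
subject means).  Significance uses a paired two-sided Wilcoxon signed-rank
test across subjects by default (robust at cohort sizes near 11), with a
paired t-test as an option; identical accuracy vectors return p = 1 by
convention.

## Complexity accounting

`count_params` counts from the symbolic layer trace (convolutions
bias-free, batch norm contributing 2 trainable values per map plus 2
stored running statistics); `count_flops` counts inference operations per
trial with a declared convention — `mac2` (default) scores a multiply-add
as 2 FLOPs, `mac1` as 1.  Average pooling costs window−1 additions plus
one divide per output; ELU one operation per element; softmax 3N.  Bytes
are parameters × 4 (float32).  Published complexity figures for this
architecture family are not asserted anywhere: they depend on the (C, T)
used for counting, which such tables rarely state.

## Problem sizes and numerical choices

Study-scale runs use C = 64, T = 300 (3 s at 100 Hz), 60 trials/subject,
5 source subjects (300 pooled pre-training trials), 20 split seeds for the
recovery and transfer studies, and 5 seeds for the label-permutation
control.  Weights are float32; optimizer state float64.  Seeded
`numpy.random.Generator` streams drive initialization, shuffling, dropout
and the generator; one global seed fans out to stages via a CRC32 hash of
the stage name, so every stage is independently reproducible.  Determinism
is bit-exact on a fixed platform (same BLAS/FFT libraries).

## Known limitations

* The NumPy engine targets this architecture family, not general networks;
  only the layer vocabulary above is implemented.
* The EDF writer emits a minimal single-record EDF+C file — sufficient for
  round-tripping recordings and annotations, not a general-purpose
  exporter; recording durations must fit the 8-character duration field.
* The simplified 1-D topography means spatial filters learned on synthetic
  cohorts are not anatomically interpretable.
* Transfer results on synthetic cohorts are directional evidence (ordering
  of protocols), not effect-size estimates for clinical data.
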