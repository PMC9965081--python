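# Methods

`cefhar` implements per-frame ("classification every frame", CEF) semantic
segmentation of tri-axial wrist accelerometer streams into a background class
plus six activities (get-up, laying, stand-up, picking, sitting, walking),
together with the sliding-window (SW) baseline it is compared against, a
leave-one-subject-out (LOSO) evaluation harness, and a synthetic data
generator that stands in for the private wrist-sensor recordings the approach
targets.

## The per-frame model

Input is a recording `X ∈ R^(T×3)` (acceleration in g at 15 fps); output is a
class distribution per frame.  The network stacks `n_blocks = 3` identical
structures, each composed of:

1. **Multi-kernel feature extraction.**  Five parallel 1-D convolution
   branches with kernel widths 5, 10, 20, 50, 100 give receptive fields from
   ⅓ s to ~6.7 s; each branch is conv(k) → batch-norm → layer-norm → ReLU
   followed by two width-1 convolutions with the same norm/activation
   pattern.  Branch outputs (64 channels each) are concatenated (320
   channels) and fused by a width-1 convolution back to 64 channels.  All
   convolutions preserve T; even kernel widths pad ⌊(k−1)/2⌋ zeros left and
   the remainder right.
2. **Channel attention** (CBAM-style).  Average- and max-pooling over time
   produce two 64-vectors; both pass through the *same* bottleneck
   (width-1 conv 64→4, ReLU, width-1 conv 4→64; the squeeze conv is
   bias-free), the two maps are added, and a sigmoid yields one gate per
   channel that rescales the features.
3. **Temporal self-attention.**  Query, key and value come from three
   distinct width-1 convolutions; the raw T×T map Q·Kᵀ is squashed
   *elementwise by a sigmoid* — not a softmax — and applied to the value.
   No pooling touches the time axis, so per-frame positional information
   survives.  Optional 1/√F score scaling exists behind a flag and is off by
   default.  Each block closes with one further batch-norm + layer-norm pair.

A per-frame affine head (width-1 conv, 64→7) and a per-frame softmax produce
the output.  Prediction is the per-frame argmax with ties broken toward the
lowest class index.

**Normalization dialect and the parameter checksum.**  The canonical
configuration uses layer normalization with an elementwise affine over the
whole (channels × time) feature map, built for the protocol length T = 250
(2·64·250 = 32,000 parameters per instance).  Under that dialect — together
with the bias-free squeeze conv and the block-closing norm pair above — the
canonical network has exactly **3,416,583** learnable parameters
(`cefhar.count_parameters`, itemized by `cefhar.parameter_ledger`).  The
(C×T) affine ties those layers to a fixed sequence length, so the package
also provides a per-channel layer-norm mode (statistics and affine over
channels, independently per frame) that is shape-free in T; variable-length
invariants and the desk presets use whichever fits the experiment.

**Loss.**  Training minimizes the cross-entropy *summed* over frames,
`L = −Σ_{j≤T} Σ_{i≤C} y_ji log z_ji`, and summed over the recordings of a
batch (no averaging), so every frame carries the same weight regardless of
batch size.  Log arguments are clamped at 1e−12.  Optimization is Adam at
learning rate 1e−3; the full protocol is 200 epochs at batch 100, the desk
preset 30 epochs at batch 16.  No validation split, early stopping, weight
decay, dropout or augmentation is used.

## Sliding-window baseline

Recordings are cut into fixed windows (canonical size/overlap pairs 10/5,
20/10, 40/20 frames), each labelled with its majority (plurality) class, ties
toward the lower index.  The window classifier reuses the same stacked blocks
truncated by global average pooling over the window and an affine head, and
is trained with the same protocol.  At prediction time every frame takes the
class of its most confident covering window (confidence = maximum softmax
probability; ties toward the earlier window), classes are expanded over the
window extent, and trailing frames not coverable by a full window (e.g.
frames 240–249 at T = 250 for 40/20) inherit the nearest covered frame's
assignment.  Windows are full only: the number of windows is
⌊(T − size)/stride⌋ + 1.

## Evaluation

All scoring is frame-level for both methods: a pooled confusion matrix (rows
true, columns predicted), per-class precision/recall/F1 with the 0/0 → 0
convention, and macro averages over all seven classes including background.
LOSO folds hold out every recording of one subject; the cross-fold summary is
the unweighted mean of fold macro-F1.

## Synthetic data generator

The generator replicates the collection protocol of the study dataset (which
is private): 8 subjects × (6 single-activity + 12 ordered two-activity
scripts) × 10 repetitions, each a 250-frame recording at 15 fps — 1440
recordings, 180 per subject — with activities at varying onsets and dense
per-frame labels.

Signals follow a gravity-orientation model in units of g.  Postures map to
unit gravity directions in the sensor frame (standing (0,0,1), seated
(0.6,0,0.8), lying (1,0,0)); a transition activity is a smoothstep
reorientation ramp between its start and end posture plus a transient bump;
picking is an out-and-back excursion toward a bent-over direction; walking is
a quasi-periodic oscillation (base step frequency 2 Hz, first harmonic)
around standing.  Oscillatory components carry brief trapezoidal on/off
envelopes (≈3–5 frames) that vanish exactly at the segment endpoints: the
segment joins the surrounding background continuously, yet nearly every
labelled frame carries activity-level signal energy, keeping the label
sequence and the signal coupled.  Background is the current posture
plus a small slow orientation wobble (amplitude 0.004 g at 0.1 Hz, so "no
movement" is never exactly constant) and white per-axis sensor noise
(σ = 0.03 g).  Transitions last 15–45 frames (1–3 s), walking 45–120 frames;
per-subject amplitude/frequency/duration scales are drawn once per subject
from ±15–20 % ranges.  Orientation is continuous across segment boundaries:
each segment starts from whatever posture the previous one left.

Every sample draws from an independent random stream keyed by
(seed, subject, script, repetition), so datasets are bit-reproducible and
order-independent.

**What the generator does and does not emulate.**  It reproduces the
protocol grid, the gravity structure of wrist accelerometry, class
separability, brief transitions, subject-level variation and label/signal
coupling.  It does not attempt biomechanical realism: real wrist data have
heavier-tailed noise, orientation drift within activities, inter-repetition
variability far beyond amplitude scaling, and labelling uncertainty at
boundaries.  Passing tests on this generator therefore demonstrate that the
pipeline learns and evaluates what it claims to — not that absolute scores
obtained here transfer to real recordings.

## Numerical and design choices

- Norm order inside a conv unit is conv → batch-norm → layer-norm → ReLU;
  the order is fixed by convention here and switchable to identity in test
  mode for oracle comparisons.
- Batch-norm uses per-channel statistics over (batch, time); at inference it
  uses running averages that are *recalibrated* after training — one
  deterministic pass over the training set re-estimates the statistics at the
  final weights, removing the lag of the exponential averages after short
  runs.  The per-frame model and every window classifier are treated
  identically.
- Self-attention scores use no 1/√d scaling by default and sigmoid rather
  than softmax, so score rows do not sum to one; the block-closing norms
  keep magnitudes controlled.
- No residual connections anywhere.
- Weight initialization is uniform fan-in (±1/√fan_in) from a recorded seed;
  the per-frame head and every window classifier derive per-fold seeds
  deterministically from the protocol seed.
- The window-classifier batch size defaults to 16× the sample-level batch
  because windows are an order of magnitude shorter than recordings.
- 0/0 metric cells yield 0; macro averages include the background class.
- Degenerate inputs: single-frame sequences are legal everywhere
  (self-attention reduces to a 1×1 score); empty datasets, mixed-length
  batches, non-finite inputs and out-of-range labels raise immediately.

## Desk-scale problem sizes

The repository's tests and examples run the full pipeline at reduced sizes
chosen as the package's own desk presets: the tiny model (16 filters, one
block, reduction 4), 30-epoch training, and 2-subject LOSO subsets of the
default 1440-recording dataset.  The canonical full-size configuration is
exercised structurally (construction, parameter accounting, forward passes);
its 200-epoch/8-fold training protocol is available through the same API for
larger machines.

## Known limitations

- The network is numpy-based and single-threaded BLAS-bound; it is meant for
  research-scale experiments, not production throughput.
- The canonical layer-norm dialect fixes T = 250; cross-length transfer
  requires the per-channel dialect.
- With sigmoid (unnormalized) attention scores, each output frame's features
  scale with T; models trained at one length should not be applied at a very
  different length even in the per-channel dialect.
- Desk-scale training exhibits noticeable run-to-run variance in held-out
  macro-F1 (the optimization budget is small); the experiment protocols fix
  seeds and report per-fold values.
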