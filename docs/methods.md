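# Methods

## The model

`parconvnet` implements a small convolutional network for medical image
patch classification, built from three ideas that work well together at low
parameter budgets: parallel convolution branches with mixed receptive
fields, residual connections realized as an extra concatenation input, and
a global-average-pooling (GAP) head that decouples the classifier from the
input resolution.

The canonical network (returned by `lightweight_architecture`) is:

```
input (H x W x 3)
C1: 3x3 conv, stride 1, 32ch        -> H x W x 32
C2: 5x5 conv, stride 2, 32ch        -> H/2 x W/2 x 32
block 1: [1x1 | 3x3 | 5x5 | 7x7] conv, stride 1, 32ch each,
         + pass-through of the C2 output (residual)
         concat (5 inputs)          -> H/2 x W/2 x 160, then BN (B1x)
block 2: [1x1 | 3x3 | 5x5 | 7x7] conv, stride 2, 64ch each,
         + C11: 3x3 stride-2 32ch projection of the block-1 output
         concat (5 inputs)          -> H/4 x W/4 x 288, then BN (B2x)
GAP -> FC(200) -> dropout(0.5) -> FC(n_classes) -> softmax
```

Every convolution is followed by batch normalization and ReLU.  All
convolutions use "same" padding, `out = ceil(in / stride)` per axis, which
is the only convention consistent with the layer table this architecture is
specified by (224 -> 224 at stride 1, 224 -> 112 at stride 2); non-square
inputs are handled per axis.  The published layer table prints the block-2
concatenation as 228 channels, but the listed branch widths (4 x 64 plus
the 32-channel projection) force 288; we treat 228 as a transposition
misprint and implement 288.  The same table describes the feature layer
used for the SVM stage as "the last fully connected layer (FC2)", which has
only `n_classes` units; the 200-unit FC1 is the plausible intent and is the
default feature tap (any named layer can be selected instead).

Total trainable parameters: 1,079,258 for 2 classes, independent of input
size (fully convolutional body + GAP).

## Engine

No deep-learning framework is used: the forward/backward passes
(convolution via im2col + BLAS GEMM, batch norm, ReLU, concatenation, GAP,
fully connected layers, inverted dropout, softmax cross-entropy) are
implemented directly on numpy arrays (NHWC, float32).  Backpropagation was
verified against central-difference numeric gradients in float64 (relative
error below 1e-6 on all parameter groups with non-negligible gradients).
On one CPU the network is memory-bandwidth bound, so layers keep persistent
scratch buffers reused across steps; an activation tapped from the network
must be copied if it needs to outlive the next forward call (the feature
extractor does this).

Choices the architecture description leaves open, and what we picked:

* weight init: He-normal for convs and FC layers (ReLU network), seeded;
* input scaling: pixel values mapped to [0, 1];
* BN inference statistics: running mean/var with momentum 0.9;
* loss: categorical cross-entropy (softmax head);
* "dropout layer with learning rate 0.5" is read as dropout probability 0.5;
* block 2's projection conv consumes the B1x output (the table does not say
  which tensor it taps).

## Training protocol

Defaults mirror the reference protocol: SGD with momentum 0.9, mini-batch
32, up to 100 epochs, initial learning rate 0.001, constant schedule (a
step decay is available but off), shuffle each epoch, no early stopping and
no validation split.  Splits are stratified with a floor-to-train rounding
rule (0.8 on 100 balanced two-class records gives exactly 40/10 per class;
0.55 on 4,000 gives 2,200/1,800).  Training is bitwise reproducible given
(data, config, seed); non-finite loss raises immediately instead of
corrupting weights.

The same-domain transfer chain (`same_domain_tl`) is: (A) train from
scratch on the pooled source manifests under the source vocabulary; (B)
carry the body over bit-exactly, replace the FC head for the target
vocabulary, fine-tune on the target train split (optionally with the body
frozen); (C) evaluate on the target test split.  Augmentation is applied
after splitting, never to test records, to exclude leakage — the reference
description ("55% (adding augmented images) for training") does not fix the
order, and augment-after-split is the conservative reading.

## Metrics

Accuracy, specificity, recall, precision and F1 are computed from TP/TN/FP/FN
on the percent scale, with full precision internally and one-decimal
rounding only at serialization.  Zero-denominator metrics are reported as
undefined (flagged `None`), never coerced to 0 or 100.  Multiclass scalars
are macro averages of one-vs-rest per-class values; the per-class breakdown
is always retained so any other aggregation can be recomputed.  Which class
is "positive" in a binary task is a caller choice (the disease class by
convention).

## Augmentation

Operators: rotation (right angles {90, 180, 270} plus uniform ±15° jitter),
horizontal/vertical flip, zoom 0.85–1.15, crop fraction 0.8 with resize
back, brightness ±15% of full scale, contrast 0.8–1.2.  The operator *set*
is prescribed by the reference protocol; the magnitudes are not, so these
defaults are chosen as conventional mild photometric/geometric jitter and
are fully configurable.  `expand_dataset` draws one operator uniformly per
augmented copy; `balance_classes` augments minority classes up to the
majority train count.  Only train records are ever augmented.

## Synthetic data

The generators emulate the class-conditional *structure* of the three
tasks, not their photorealism:

* **cells** (80×80, circular / elongated / other): single stained-cell
  images on a pale background; circular cells are low-eccentricity discs
  with central pallor, elongated (sickle-like) cells have an axis ratio
  growing with separability, "other" cells are irregular multi-harmonic
  blobs with granular interior texture.
* **ulcer** (224×224, normal / abnormal): skin-toned texture with smooth
  shading; abnormal patches blend in a dark-red irregular wound whose
  grayscale contrast against the skin is at least `0.25 × separability`.
* **lesion** (500×375, benign / malignant): a central pigmented blob;
  malignant lesions add first-harmonic asymmetry, high-frequency border
  irregularity and a second darker tone — the ABCD-rule cues — with
  magnitudes scaling with separability.  An imbalance ratio option shrinks
  the malignant class to exercise balancing.

`separability` in (0, 1] scales how far the class-conditional parameter
distributions sit apart (1 ≈ zero Bayes error); `noise_level` adds pixel
noise after the geometry is drawn, so it perturbs pixels without moving
class structure.  Generators are pure functions of their spec: identical
specs give byte-identical PNGs.  Because the cues are deliberately strong
and low-dimensional, passing the learnability checks below shows that the
pipeline trains and generalizes correctly — it says nothing about accuracy
on real clinical images.

## Desk-scale checks

The self-contained checks in `tests/test_acceptance.py` use problem sizes
chosen to run on one CPU: 64×64 inputs, 100 images per class, 10 epochs for
the learnability and hybrid checks; 32×32 inputs for the transfer-direction
check (300 source images, a 42-image target train split).  For these short
schedules the learning rate is 0.01 rather than the 0.001 default, which is
calibrated for ~100-epoch runs.  Observed behaviour: ≥95% test accuracy on
all three well-separated tasks, chance-level accuracy under permuted
labels, transfer-chain accuracy ≥ from-scratch accuracy on the small
target, and an SVM on FC1 features within 2 accuracy points of the softmax
head.

## Known limitations

* The engine is CPU-only and single-threaded beyond BLAS; it is meant for
  desk-scale experiments, not production training.
* BN statistics on very small batches are noisy; for datasets of a few
  dozen images, full-batch training is more stable.
* `train` updates the passed network in place (it is also returned);
  callers wanting to keep the initial state should checkpoint first.
* The ECOC multiclass SVM uses scikit-learn's one-vs-one reduction, which
  matches the default coding of the reference implementation but does not
  expose custom code matrices.
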