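# Methods

`swefuse` implements a multimodal breast-lesion classification protocol:
a discriminative convolutional network applied to paired B-mode
ultrasound (US) and shear-wave-elastography (SWE) images, three ways of
combining the two modalities, a repeated-split evaluation scheme, and a
z-score significance test of the resulting metrics. Because the clinical
cohort this protocol was designed around (746 images, 486 malignant /
260 benign, 207 patients) is private, the package ships a synthetic
phantom generator that reproduces the *statistical structure* of that
data so every pipeline stage is executable and testable end to end.

## The classifier

The network is a four-convolution stack for `(224, 224, 3)` inputs:

| layer | filters/units | kernel | padding | stride | activation |
|---|---|---|---|---|---|
| Conv2D | 64 | 11×11 | same | 4 | ReLU |
| MaxPool2D | – | 3×3 | valid | 2 | – |
| BatchNorm | – | – | – | – | – |
| Conv2D | 128 | 5×5 | same | 1 | ReLU |
| MaxPool2D | – | 3×3 | valid | 2 | – |
| BatchNorm | – | – | – | – | – |
| Conv2D | 256 | 3×3 | same | 1 | ReLU |
| Conv2D | 256 | 3×3 | same | 1 | ReLU |
| MaxPool2D | – | 3×3 | valid | 2 | – |
| Dropout | – | – | – | – | – |
| Flatten | – | – | – | – | – |
| Dense | 1024 | – | – | – | ReLU |
| Dense | 1 | – | – | – | Sigmoid |

At 224×224 the spatial trace is 56 → 27 → 13 → 6, giving a 9216-long
flattened feature vector. Training uses Adam (learning rate 1e-4),
binary cross-entropy, batch size 32 and up to 100 epochs; accuracy and
AUC are tracked per epoch.

The network is implemented directly in NumPy (im2col convolution with
TensorFlow-style `same` padding, valid max-pooling, batch normalization
over the channel axis with momentum 0.99 and eps 1e-3, inverted
dropout, Adam with eps 1e-7). Correctness of backpropagation is
guarded by finite-difference gradient tests over every layer type.
All randomness — initialization, shuffling, dropout — flows from
explicit seeds, so training is bitwise reproducible in a
single-threaded process.

Choices the protocol leaves open, and the defaults taken here:

* **Dropout rate** — unspecified; default 0.5, configurable.
* **Pooling padding** — valid (no padding), consistent with the
  stride-4 / pool-3 design the layer table mirrors.
* **Model selection** — the protocol says only that validation data
  tuned the model; default is to keep the weights of the epoch with the
  best validation loss (`checkpoint="best_val_loss"`), with
  `"last"` available.
* **Class weighting** — none by default despite the 486/260 imbalance
  (matching the protocol's silence); a `class_weight` option exists.
* **Weight initialization** — He for ReLU layers, Glorot for the
  sigmoid head, seeded.

## Reduced-scale protocol

The full protocol (224×224, 100 epochs) is far too heavy for routine
testing on one CPU, so experiments and tests run a reduced protocol:
64×64 inputs (the smallest size the pooling stack admits is ~52 px),
8 epochs, learning rate 1e-3, batch-norm momentum 0.8. The learning
rate and momentum are scaled because the reduced runs take tens of
optimizer steps instead of ~1700: with momentum 0.99 the inference-time
running statistics never approach the batch statistics and the network
appears untrained at evaluation, and 1e-4 cannot traverse the loss
landscape in 8 epochs. The architecture, loss, optimizer, batching and
checkpointing are unchanged.

## Combining US and SWE

* **Generalized** — one classifier trained on the pooled stack of US
  and SWE rows (training and validation sets are therefore exactly
  twice the paired size; the test set is not pooled). Prediction feeds
  both images through the one model and averages the two probabilities.
* **Ensembled** — two classifiers of identical architecture, one
  trained per modality (seeds `s` and `s+1`); prediction averages their
  probabilities. With identical component models this degenerates
  exactly to the single-model prediction.
* **Parallel** — two identical *headless* trunks (the classifier minus
  its final sigmoid unit, so each emits 1024 features), one per
  modality; features are concatenated into a 2048-vector feeding a
  single shared sigmoid unit, trained end to end. This method requires
  both modalities at prediction time. The combiner is read minimally as
  concatenation; trunk weights are not shared.

Both averaging fusions are symmetric and bounded by their component
probabilities. The decision threshold everywhere is 0.5.

## Evaluation protocol

70/15/15 train/validation/test split with largest-remainder
apportionment (which maps 746 → 522/112/112 exactly), seeded shuffling,
stratified by class by default; per-class rounding is reconciled so the
overall sizes always hit the largest-remainder targets. A lesion's US
and SWE images always travel together (they are one sample). The model
build and evaluation repeat 20 times (runs `r` use seed
`master_seed + r` for a fresh split and fresh initialization — the
maximal-variance reading of "repeated"; a fixed-split mode is
available), and metrics are summarized as mean and sample SD (ddof 1).
An image-level split can place one patient's images in different
partitions; a `patient_level` grouping that assigns whole patients to
one partition is provided to avoid that leakage, at the cost of
approximate sizes.

Metrics: accuracy, sensitivity (malignant = positive class),
specificity at threshold 0.5, and rank-based AUC (ties count ½,
verified in tests against exhaustive pair counting).

## Significance testing

For a reference value `x` (e.g. the expert radiologist's accuracy) and
repeated-run summary (μ, σ), the statistic is `Z = (x − μ)/σ` with a
standard-normal p-value; `p < 0.05` (strict) is significant. The
default is two-sided. The published benchmark's superior-to-expert
markers regenerate under both one- and two-sided conventions; the
superior-to-single-dataset markers regenerate under the two-sided
convention only (one-sided would additionally flag the parallel
method's accuracy against US, |z| = 1.80, which the benchmark does not
mark — evidence the original test was two-sided). No multiple-testing
correction is applied, matching the protocol; the output table records
this.

## The phantom generator

Each sample is built from an explicit seed:

* **B-mode** — smooth background echogenicity (level 0.55 ± 12 %
  low-frequency field) times unit-mean gamma multiplicative speckle
  (scale 0.25); a hypoechoic lesion (echogenicity factor 0.45) whose
  boundary is a rotated ellipse (radius 14–26 px in a 112×144 image)
  radially perturbed by low-order Fourier modes with RMS amplitude
  0.18 (malignant) vs 0.10 (benign); and a posterior attenuation
  contrast that ramps up over 30 px of depth below the lesion —
  acoustic shadowing for malignant masses (strength 0.35), posterior
  enhancement for benign ones (−0.15), per-lesion SD 0.10. Both are
  canonical sonographic signs.
* **SWE** — identical to the B-mode outside the radiologist-style ROI
  rectangle (lesion bounding box plus a random 4–12 px margin on three
  sides and a tight 2–6 px distal margin, as elastogram boxes are
  drawn); inside it, a stiffness field (arbitrary kPa-like units:
  background 12, lesion mean 45 vs 30 with a per-lesion random effect
  of SD 10, within-lesion heterogeneity 18 vs 8, smoothed by masked
  normalized convolution so the lesion-interior expectation is exactly
  the drawn mean) rendered through a jet colormap scaled to 100 and
  alpha-blended at 0.5 over the grayscale.
* **Cohorts** — class counts are exactly `round(n · balance)` with the
  clinical 486/746 default; images group into patients (207 per 746 by
  default, 2–6 images each) sharing one label and correlated lesion
  geometry.
* **Screenshots** — the two panels are placed side by side or stacked
  on a dark bezel with randomized margins and bright label-like
  clutter; panel pixels are copied verbatim so cropping is bitwise
  invertible, and all boxes are recorded.

The class contrasts are deliberately *partial*: per-lesion random
effects (stiffness mean, posterior-effect strength) make the class
distributions overlap, so no single cue is perfectly separable — the
regime in which combining modalities can help, and the regime the
clinical data occupies.

The fusion-recovery experiment additionally runs the generator in a
*modality-separated* configuration: boundary irregularity equal across
classes (0.12), so the US images discriminate only through the
posterior attenuation contrast — which, being depth-ramped and distal
to the tightly drawn ROI, lies almost entirely outside the elastogram
rectangle — while the SWE images add the stiffness contrast. This is
what makes whole-image variants outperform region-only crops there
(region-only crops magnify the lesion but lose the posterior field),
reproducing the ordering the clinical benchmark reports: RE-US worst,
then RE-SWE, then US/SWE, with fusion matching or beating the best
single modality.

Two robustness notes from surveying the experiment across master
seeds: the US > RE-US gap and the fusion margin are large and stable,
but SWE vs RE-SWE is nearly balanced — the elastogram crop keeps the
entire stiffness cue (and magnifies it), losing only the posterior
field — so that ordering, while holding on average, can reverse on
individual repetitions. The clinical data's stronger whole-image
advantage presumably rests on context cues (tissue architecture,
lesion surroundings) the phantom does not model.

What the generator does **not** emulate: acoustic wave propagation,
scanner-specific texture, JPEG artifacts of real screenshots, lesion
types beyond one mass per image, and reader variability. Passing the
synthetic recovery experiment therefore shows the *pipeline* recovers
configured contrasts with the expected ordering of methods; it says
nothing about clinical performance, which is why the clinical metric
table enters the package only as published constants for the
significance machinery.

## Numerical and degenerate-input conventions

* Rectangles are 0-based half-open `(row_start, col_start, row_stop,
  col_stop)` everywhere.
* Resizing: bilinear, Gaussian anti-alias blur only when downscaling
  (σ from the scale factor, via scikit-image); grayscale replicated to
  3 channels; output clipped to [0, 1]. Square resizing intentionally
  distorts aspect ratio — that is the studied protocol.
* AUC requires both classes present; single-class inputs raise an error
  naming the undefined metric.
* `sigma = 0` makes the z-test degenerate; table rows report
  `"degenerate"` status instead of a value.
* Ties at the 0.5 threshold count as positive predictions.
* Images are stored as 8-bit PNG (lossless); round trips are exact to
  0.5/255.

## Problem sizes used in tests and the acceptance script

The recovery experiment runs 200 phantoms, 5 repeated splits, 64×64
inputs, 8 epochs — sizes chosen so the full suite completes in minutes
on one CPU while keeping ~30 test samples per run for stable AUCs. The
end-to-end reproducibility check uses 60 phantoms, 3 runs, 3 epochs.
The clinical split/pooling arithmetic and the significance regeneration
are exact and instantaneous at the published sizes (n = 746, 20 runs).
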