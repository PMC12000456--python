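# Methods

## Problem and model

`cystodx` classifies endoscopic bladder tissue images into four grades
(HGC, LGC, NST, NTL) with an ensemble of three independently trained
classifiers whose votes are combined by a two-scenario rule. The design
assumption behind the ensemble is error diversity: the members share the
task but differ in capacity, input resolution and training data (plain,
GAN-augmented, attention-cropped), so coincident errors are less likely
than individual ones.

### Outlier rejection

Before any training, every image is mapped to a scalar feature and the
interquartile fence `[Q1 − m·IQR, Q3 + m·IQR]` (default m = 1.5) is
computed over the *whole* dataset; images outside the fence are dropped.
Choices pinned here:

- **Quartile convention.** Linear interpolation at position `p·(n−1)`
  (numpy's default). Any convention would work; one is pinned so tests can
  assert exact values.
- **Closed fences.** A value exactly on a fence is kept: the rejection rule
  reads "outside the range", and the degenerate all-identical case (IQR = 0)
  then correctly keeps everything.
- **Single gate before splitting.** Fences are computed once over all
  records, not per split, so train/validation/test see the same criterion.
- **Feature.** Default is mean brightness, which directly targets exposure
  artifacts. The alternative `embedding` mode runs a fixed-seed untrained
  convolutional encoder and reduces the feature vector by its L2 norm; it
  is a random-projection feature, deterministic across runs, and is the
  hook where a pretrained backbone could be substituted.

### CNN branch

Input 32×32×3, two 5×5 valid convolutions (8 and 16 filters) each followed
by ReLU and 2×2 max pooling — spatial chain 32→28→14→10→5 — then dense
400→120→84→C with softmax. Loss is categorical cross-entropy (forced by the
softmax output). Optimization is SGD (lr 0.01, batch 32) with classical
momentum 0.9; inputs are centered to [−0.5, 0.5]. Both additions matter in
practice: with raw [0,1] inputs and no momentum the net sits at the uniform
softmax for many epochs. The dense head width follows from the 5×5×16 = 400
flatten; alternative widths are configurable.

### GAN branch

One unconditional generator/discriminator pair per class — the minimal
labeling-sound choice, since an unconditional GAN trained on one class can
only emit that class's label. The discriminator trains on the standard
binary cross-entropy form of the minimax value; the generator uses the
non-saturating surrogate (maximize `log D(G(s))`), the standard trainable
form of the minimax objective. Discriminator outputs are clamped to
`[1e-7, 1 − 1e-7]` so the logged value `V(D,G)` stays finite; `V ≤ 0`
always, with equality −2·log 2 at `D ≡ 1/2`. Defaults: latent dimension 32,
plain SGD (lr 0.05, batch 16), 400 alternating steps at desk scale, and as
many synthetic images per class as the smallest real class in the train
split. Synthetic images are appended to the train split only and flagged in
the manifest; validation and test are never touched.

### XDL branch

A VGG16-shaped backbone: five blocks of 3×3 same convolutions
(2/2/3/3/3 layers; widths 64·m…512·m for a multiplier m), 2×2 max pooling
after each block, Global Average Pooling, one dense layer, softmax. At
m = 1 and 224×224 input this reproduces the classical 224→112→56→28→14→7
chain; the desk-scale default is m = 0.125 at 64×64.

Saliency definitions:

- `y^c` is the **pre-softmax** class score. The usual CAM practice; the
  softmax-gradient alternative only rescales maps and can vanish for
  confident predictions.
- Grad-CAM weights are spatial means of `∂y^c/∂A^k` over the chosen layer
  (default: the ReLU output of the last convolution); the map is the
  ReLU-clipped weighted sum of the feature maps, at feature resolution.
- Guided backprop gates every ReLU's backward pass on *both* positive
  forward activation and positive incoming gradient; the resulting input
  gradient is clipped at zero and reduced to one channel by a per-pixel max
  over RGB. The clip is part of the rule: the map answers "which pixels
  positively support this class".
- Guided Grad-CAM multiplies the guided map with the Grad-CAM map after
  **align-corners bilinear** upsampling to input resolution — the only
  dimensionally coherent way to combine the two resolutions, and exactly
  testable. Its support is therefore contained in the upsampled Grad-CAM
  support. The per-class mean (`aggregate_guided_grad_cam`) is exposed for
  visualization but not used in training, where the predicted-class map is
  the natural attention signal.

Training: epoch 1 warms up on the original images; from epoch 2 each epoch
recomputes every training image's Guided Grad-CAM map for its currently
predicted class, crops the bounding box of pixels ≥ 0.5 of the map maximum
(4 px margin), resizes back, and trains on originals plus crops. "Train
until the best weights" is interpreted as early stopping on validation
accuracy with patience 3, returning the best-validation checkpoint. The
optimizer is Adam (lr 1e-3): thirteen unnormalized conv layers trained from
scratch make essentially no progress in 10 epochs under momentum-SGD
(≈0.53 validation accuracy on the fixtures vs ≈1.0 with Adam); Adam is the
standard remedy when batch normalization is out of scope.

### Vote

With exactly three members: unanimity and 2-vs-1 agreement follow the
majority; three-way disagreement falls back to the member with the highest
stored validation accuracy. Two interpretations of "accuracy" ship because
both are natural: `overall` (one validation accuracy per member, the
worked-example behaviour) and `per_class` (the member's validation recall
on its own predicted class). Accuracy ties break by a fixed precedence
(default XDL > GAN > CNN, the branches' typical quality ordering;
configurable). The Majority Fault Problem — the dissenting member being
strictly more accurate than both agreeing members — is flagged and logged
but never overrides the majority: the method's answer to MFP is choosing
members of similar accuracy, not a different rule.

### Metrics

Rows of the confusion matrix are true classes, columns predictions.
Per-class one-vs-rest counts give precision and recall; macro averages are
unweighted means; micro averages pool the counts (for single-label data
micro precision = micro recall = accuracy, an identity the tests assert);
error = 1 − accuracy; F1 is the harmonic mean of macro precision and macro
recall (a single multi-class P and R are otherwise undefined). Zero
denominators yield 0 and are logged.

## Synthetic fixtures

The generator emulates what the pipeline needs from real cystoscopy data,
not its appearance:

- class-discriminative structure — NTL: smooth low-frequency background;
  NST: + fine grating texture (~0.7 rad/px, chosen to survive the 2×
  downsample to the CNN input); LGC: + one bright disc lesion (contrast
  0.25), mask = disc; HGC: + irregular blob (radius perturbed ±25%
  sinusoidally, contrast 0.4, interior speckle), mask = blob;
- lesions carry ground-truth masks so saliency localization is checkable;
  the additive lesion profile keeps full contrast everywhere inside the
  mask (the boundary ramp lies outside it), so inside-mask mean intensity
  exceeds the background by at least half the class contrast;
- clean images have mean brightness drawn uniformly from [0.45, 0.55] — a
  bounded, tightly clustered distribution whose 1.5-IQR fences contain the
  whole clean support, so no clean image is ever rejected by construction;
- exposure outliers (mean ≥ 0.95 or ≤ 0.05, round-robin across classes,
  class label retained) sit at least 0.2 outside the clean fences.

What passing tests on these fixtures does **not** show: robustness to real
cystoscopy variability (vasculature, specular highlights, motion blur,
domain shift between patients), behaviour under class imbalance at clinical
ratios, or that the reported accuracies transfer to any real dataset.

## Problem sizes and numerical choices

The default study configuration is 100 images per class at 64×64 with 10%
outliers, a 0.7/0.15/0.15 stratified split, 10 epochs per branch, 400 GAN
steps per class — sizes at which the whole pipeline runs in a few minutes
on one CPU while every behavioural property (separability, outlier margin,
localization) is measurable. All randomness flows from a single integer
seed through `numpy.random.default_rng`; reruns are bit-reproducible on a
fixed platform. Float32 is used throughout the networks; quartiles and
metrics are float64. Argmax ties resolve to the lowest class index.
Degenerate attention crops fall back to the uncropped image and are logged.

## Known limitations

- The numpy engine is CPU-only and stride-1; it is sized for the desk-scale
  study, not for 224×224 training at m = 1 (which it supports functionally
  but slowly).
- GAN sample quality is not scored (no FID/IS); the augmentation guarantee
  is label soundness and split hygiene, not realism.
- The `embedding` outlier feature uses an untrained encoder; with only
  exposure outliers present, mean brightness is the stronger default.
- Multivariate outlier detection, soft/probability voting and stacking are
  deliberately out of scope.
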