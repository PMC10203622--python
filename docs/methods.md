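# Methods

## Problem and model

Retinal vessel segmentation is per-pixel binary classification of fundus
photographs into vessel vs background. Two properties make it hard:
vessels are a small minority of pixels (roughly 1:10 against background
within the field of view), and the clinically interesting structures —
thin, low-contrast branches and vessels crossing the over-illuminated
optic disc — are exactly the ones a plain cross-entropy model learns last.

`vesselseg` implements a coarse-to-fine cascade of two *identical*
residual U-shaped backbones:

1. **Coarse stage** — reads the RGB image and predicts a rough vessel
   probability map `P_c`.
2. **Inter-stage attention gate (ISAM)** — channel-average and
   channel-max pooling of `P_c` are concatenated (2 channels) and passed
   through three parallel 3x3 convolutions with dilation rates 1, 2 and 3
   (padding = rate, no bias); their sum is batch-normalised and passed
   through a sigmoid, giving a spatial gate `s ∈ (0,1)^{H×W}`. The gated
   map `s ⊙ P_c` emphasises coherent vessel regions within an effective
   7x7 context window.
3. **Fine stage** — reads `concat(image, s ⊙ P_c)` and predicts the final
   map `P_f`, giving pixels the coarse stage misclassified a second
   chance.

Each backbone is an encoder-decoder with two stride-2 downsampling
convolutions and channel schedule (32, 64, 128); residual blocks
(conv3x3–BN–ReLU–conv3x3–BN plus identity or 1x1-projected shortcut, ReLU
after the addition) at every resolution on both sides; bilinear 2x
upsampling with skip-connection concatenation in the decoder; and a 1x1
convolution + sigmoid head. Downsampling convolutions carry BN + ReLU.
Deliberately shallow (only two poolings) so thin-vessel geometry survives.

**Backbone input symmetry.** Both stages take a 4-channel input
`concat(image, prior)`. The fine stage's prior is the gated coarse map;
the coarse stage, which has no earlier prediction, receives a constant
0.5 (uninformative) prior. This makes the two backbones literally
identical in architecture and parameter count and keeps ablation variants
comparable; an extra constant channel only shifts the first convolution's
effective bias.

## Supervision

Training uses deep supervision: `L = L_main + λ · L_aux` with
`L_main = PIB(P_f, Y)`, `L_aux = PIB(P_c, Y)` and λ = 1.0 by default.
The auxiliary path shortens the gradient route into the coarse backbone
of a cascade that is effectively twice as deep as a single U-Net.

### Pixel-importance-balanced (PIB) loss

For each pixel, `num` = number of vessel pixels in the 5x5 box centred on
it (centre included; out-of-image cells contribute 0, consistent with
zero-padded images). The cross-entropy weight is

    w(i,j) = -num·0.04 + 2   if Y(i,j) = 1   (vessel)
    w(i,j) =  num·0.04 + 1   if Y(i,j) = 0   (background)

so thin-vessel pixels (small `num`) approach weight 2 while thick-vessel
interiors (`num` = 25) fall to 1, and background pixels rise from 1 with
vessel proximity — forcing predicted calibre to match the annotation. All
weights lie in [1.00, 1.96]. The weighted loss is

    PIB(P, Y) = mean_{i,j} w(i,j) · [ -Y log P - (1-Y) log(1-P) ]

Weights are computed from the ground truth only (after any geometric
augmentation), are detached from the gradient, and probabilities are
clamped to [1e-7, 1-1e-7] before the log. Box radius, slopes and
intercepts are parameters (`PIBWeightParams`) with the defaults above.

**Reduction.** The defining sum is left unnormalised in its original
statement; this package uses the *mean* over pixels (configurable to
`sum`) so the loss scale — and therefore the stated learning rate — is
independent of pad size and dataset.

## Data handling

* **Padding**: images are zero-padded to a square whose side is
  `max(H, W)` rounded up to a multiple of 16. This one rule reproduces
  both conventional pad sizes (584x565 → 592x592; 999x960 → 1008x1008).
  Padding is centred with the odd remainder to the bottom/right, recorded
  in a `PadSpec`, and inverted bit-exactly before evaluation.
* **Splits**: DRIVE-style layouts use the official 20/20 split;
  CHASE-style layouts use first-20/last-8 by lexicographic stem order,
  with the first human observer's annotation as ground truth
  (configurable).
* **Masks** are binarised at >127 of the 8-bit range on load, making the
  loader robust to antialiased annotation files.
* **Augmentation** (online, per batch): random horizontal/vertical flips
  (p = 0.5 each), rotation uniform in ±180° (bilinear for the image,
  nearest for mask/FOV), and brightness/contrast/saturation jitter with
  factor 0.2. Magnitudes are package defaults — the augmentation families
  are standard for these datasets but published recipes rarely state
  magnitudes — and all are configurable.
* **Colour**: full RGB scaled to [0, 1]; no green-channel extraction,
  CLAHE or other photometric normalisation.

## Training protocol

Adam (framework-default betas), batch size 2, initial learning rate 1e-3,
200 epochs with x0.1 decay at epochs 150 and 190, no pretraining, no
post-processing. The checkpoint kept is the *best epoch by pooled
test-set AUC* — faithful to the evaluation protocol this recipe
descends from, though optimistic as model selection; `select_by="last"`
is provided as the neutral alternative. Runs are fully seeded
(`numpy.random.SeedSequence` streams for init, batch order and
augmentation) and bit-reproducible on CPU. A non-finite loss aborts with
the epoch/step in the message.

## Evaluation

Predictions are cropped back to the original resolution, thresholded at
0.5 (`pred >= t` is vessel), and scored as SE, SP, ACC, F1 from pooled
confusion counts plus threshold-free AUC. Pixels are pooled over the
whole test set before ratios are taken (per-image reports are also
returned); the field-of-view mask, when present, excludes pixels outside
the camera aperture from all counts (`--fov {use,ignore}`). Degenerate
single-class regions yield NaN with a warning rather than a silent 0.

## Compute engine

The network runs on the package's own reverse-mode autodiff engine
(`vesselseg.nn`) over numpy: tape-based `Tensor`, convolution implemented
as a loop over kernel taps (each a batched matmul on a shifted view, so
no im2col buffer is materialised), an exact sparse-matrix adjoint for
bilinear upsampling, batch normalisation composed from primitive ops, and
Adam. Parameters are float32; gradient checks run in float64 against
central finite differences, and forward passes are verified against
nested-loop convolution and `skimage.transform.resize` oracles. The
engine is single-threaded CPU code; full-resolution (592x592) inference
works, but full-scale 200-epoch training is impractical on it — the
package's quantitative claims are therefore established at desk scale
(below).

## Synthetic data

The generator emulates the failure modes the model targets, not fundus
photorealism: branching random-walk centerlines stroked as tapered thick
trunks (3-6 px) with thin children (1-2 px) at 0.5x contrast; a smooth
reddish textured background; vessels darker than background; one bright
Gaussian disc centred on a vessel pixel; an inscribed-circle field of
view; Gaussian pixel noise (sd 0.03). Default 64x64 images carry a vessel
fraction of roughly 0.08-0.15 — the minority-class regime the PIB loss
addresses. A per-pixel stroke-width map supports stratifying metrics by
vessel calibre. All randomness derives from one integer seed through
counter-based `SeedSequence` streams; train and test sets use disjoint
streams.

What passing synthetic tests does *not* show: robustness to pathology
(lesions, haemorrhages), inter-camera colour variation, annotation
ambiguity at vessel boundaries, or true optic-disc anatomy. Results on
synthetic data establish that the mechanisms work, not clinical
performance.

## Desk-scale study sizes

The scaled-down learning check trains on 20 train / 8 test synthetic
images at 64x64 with channel schedule (16, 32, 64), 30 epochs, batch 2,
no LR decay — chosen as the smallest configuration in which the cascade,
attention gate and weighted loss all operate as designed and test AUC
comfortably exceeds 0.9. The component-ordering comparison (full model vs
single-backbone plain-CE baseline) averages best-epoch AUC over 3 seeds
under this identical budget.

## Known limitations

* The weight functions are hard-coupled to the 5x5 box through the ±0.04
  slopes; the box radius is configurable but slopes must be adjusted
  jointly (a radius-4 box can reach `num` = 81, where the vessel weight
  would go negative with the default slope; the implementation rejects
  parameter combinations that produce non-positive weights).
* Only 2x bilinear upsampling is implemented, so channel schedules are
  limited to stride-2 pyramids.
* Batch-norm running statistics come from small batches (size 2); eval
  metrics early in training lag train-mode behaviour.
* No topology-aware metrics (connectivity, centerline overlap) — scoring
  is strictly per-pixel.
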